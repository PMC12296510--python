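"""Synthetic proteomes and phosphosite tables with known ground truth.

The generator emulates the structure of a quantitative phosphoproteomics
study of phosphatase treatment: log2-scale intensities in small replicate
groups, spiked dephosphorylation effects in designated conditions,
intensity-dependent (MNAR) plus random (MCAR) missingness, phosphatase
docking motifs embedded at known offsets from their paired phosphosites,
and per-residue disorder tracks elevated over the embedded motifs.

Everything is deterministic given the config seed; each stage draws from
its own seed stream so that regenerating the proteome does not perturb the
intensity table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .slim import sample_pattern_instance
from .tables import PhosphoSiteTable, SiteKey

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ConditionSpec:
    label: str
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError(
                f"condition {self.label!r}: need >= 2 replicates "
                "(imputation eligibility requires at least two observed values)"
            )


@dataclass(frozen=True)
class EffectSpec:
    """Spiked dephosphorylation for one condition.

    ``fraction_sensitive`` of all sites receive a log2 shift drawn from
    Normal(log2_effect_mean, log2_effect_sd) relative to baseline. With
    ``sites_from`` set, the affected sites are instead a random subset
    (``fraction_of_inherited``) of another condition's sensitive sites —
    this models inhibitor protection, where only the unprotected fraction
    is still dephosphorylated in the inhibitor-treated condition.
    """

    fraction_sensitive: float = 0.1
    log2_effect_mean: float = -2.0
    log2_effect_sd: float = 0.5
    sites_from: str | None = None
    fraction_of_inherited: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fraction_sensitive", "fraction_of_inherited"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.log2_effect_sd < 0:
            raise ValueError("log2_effect_sd must be >= 0")


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness mechanism: logistic MNAR on the true value plus MCAR.

    P(missing | true value v) = logistic((mnar_midpoint - v) / mnar_slope),
    applied to the pre-noise cell value, plus an independent MCAR draw at
    ``mcar_rate``. ``mnar_slope=None`` (or inf) disables the MNAR component.
    """

    mnar_midpoint: float = 20.0
    mnar_slope: float | None = 1.0
    mcar_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.mnar_slope is not None and not math.isinf(self.mnar_slope):
            if self.mnar_slope <= 0:
                raise ValueError("mnar_slope must be > 0 (or None/inf to disable MNAR)")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must be in [0,1]")

    def p_mnar(self, value: np.ndarray) -> np.ndarray:
        if self.mnar_slope is None or math.isinf(self.mnar_slope):
            return np.zeros_like(np.asarray(value, dtype=float))
        z = (self.mnar_midpoint - np.asarray(value, dtype=float)) / self.mnar_slope
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SpacerSpec:
    """Spacer distribution: rounded Normal(mean, sd) truncated at minimum."""

    mean: float = 15.0
    sd: float = 3.0
    minimum: int = 10


@dataclass(frozen=True)
class MotifEmbeddingSpec:
    """Request ``count`` instances of a degenerate pattern written into the
    proteome, each paired with a phosphosite at a drawn spacer.

    ``placement`` is the spacer class the embedding realizes: ``upstream``
    puts the motif N-terminal of the site (site = motif end + spacer),
    ``downstream`` puts it C-terminal (site = motif start - spacer).
    """

    motif_id: str
    pattern: str
    count: int
    placement: str = "upstream"
    spacer: SpacerSpec = field(default_factory=SpacerSpec)

    def __post_init__(self) -> None:
        if self.placement not in {"upstream", "downstream"}:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class DisorderSpec:
    base_level: float = 0.2
    motif_level: float = 0.85
    noise_amplitude: float = 0.05
    flank_pad: int = 2  # residues of elevated disorder on each side of a motif


@dataclass
class SimulationConfig:
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (200, 400)
    n_sites: int = 500
    conditions: Sequence[ConditionSpec] = (
        ConditionSpec("control", 3),
        ConditionSpec("treated", 3),
    )
    effects: Mapping[str, EffectSpec] = field(
        default_factory=lambda: {"treated": EffectSpec()}
    )
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    motif_embeddings: Sequence[MotifEmbeddingSpec] = ()
    baseline_mean: float = 25.0
    baseline_sd: float = 2.5
    replicate_sd: float = 0.3
    frac_low_localization: float = 0.1
    exact_fraction: bool = True
    embedded_sites_sensitive: bool = True
    allow_tyrosine: bool = False
    background: Mapping[str, float] | None = None  # None = uniform 1/20
    disorder: DisorderSpec = field(default_factory=DisorderSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.frac_low_localization <= 1.0:
            raise ValueError("frac_low_localization must be in [0,1]")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate condition labels")
        for cond, eff in self.effects.items():
            if cond not in labels:
                raise ValueError(f"effect refers to unknown condition {cond!r}")
            if eff.sites_from is not None and eff.sites_from not in self.effects:
                raise ValueError(
                    f"effect for {cond!r} inherits sites from {eff.sites_from!r}, "
                    "which has no effect spec"
                )


@dataclass(frozen=True)
class EmbeddedMotif:
    accession: str
    motif_id: str
    start: int  # 1-based inclusive
    end: int
    site: SiteKey
    spacer: int
    spacer_class: str  # upstream | downstream


@dataclass
class Proteome:
    sequences: dict[str, str]
    disorder: dict[str, np.ndarray]
    embedded: list[EmbeddedMotif]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``sensitive`` maps condition label -> {SiteKey: true log2 effect};
    ``mechanisms`` is a site-by-sample frame of labels in
    {observed, mnar, mcar}; ``embedded`` echoes the proteome's motif record.
    """

    sensitive: dict[str, dict[SiteKey, float]]
    mechanisms: pd.DataFrame
    embedded: list[EmbeddedMotif]
    baseline: pd.Series  # per-site true baseline log2 intensity


def _background_probs(config: SimulationConfig) -> np.ndarray:
    if config.background is None:
        return np.full(20, 1 / 20)
    p = np.array([config.background.get(a, 0.0) for a in AA_ALPHABET], dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    return p


def _smooth_noise(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    raw = rng.uniform(-1.0, 1.0, size=n + 6)
    kernel = np.ones(7) / 7.0
    return amplitude * np.convolve(raw, kernel, mode="valid")


def generate_proteome(config: SimulationConfig) -> Proteome:
    """Draw random protein sequences, embed the requested motif instances,
    and lay down disorder tracks elevated over the embedded spans."""
    rng = np.random.default_rng([config.seed, 101])
    probs = _background_probs(config)
    letters = np.array(list(AA_ALPHABET))
    lo, hi = config.protein_length_range
    if lo < 3 or hi < lo:
        raise ValueError(f"bad protein_length_range {config.protein_length_range}")

    accs = [f"SYN{i:04d}" for i in range(config.n_proteins)]
    seqs = {
        a: list(rng.choice(letters, size=int(rng.integers(lo, hi + 1)), p=probs))
        for a in accs
    }
    occupied: dict[str, list[tuple[int, int]]] = {a: [] for a in accs}
    embedded: list[EmbeddedMotif] = []

    def overlaps(acc: str, s: int, e: int) -> bool:
        return any(not (e < s0 or s > e0) for s0, e0 in occupied[acc])

    for spec in config.motif_embeddings:
        motif_len = len(sample_pattern_instance(spec.pattern, rng, probs))
        for _ in range(spec.count):
            placed = False
            for _attempt in range(200):
                acc = accs[int(rng.integers(len(accs)))]
                L = len(seqs[acc])
                if motif_len > L:
                    continue
                spacer = max(spec.spacer.minimum,
                             int(round(rng.normal(spec.spacer.mean, spec.spacer.sd))))
                if spec.placement == "upstream":
                    # motif N-terminal of the site: site = end + spacer
                    max_start = L - motif_len + 1 - spacer
                    if max_start < 1:
                        continue
                    start = int(rng.integers(1, max_start + 1))
                    end = start + motif_len - 1
                    site_pos = end + spacer
                else:  # downstream: site = start - spacer
                    min_start = 1 + spacer
                    max_start = L - motif_len + 1
                    if max_start < min_start:
                        continue
                    start = int(rng.integers(min_start, max_start + 1))
                    end = start + motif_len - 1
                    site_pos = start - spacer
                span_lo = min(start, site_pos)
                span_hi = max(end, site_pos)
                if overlaps(acc, span_lo, span_hi):
                    continue
                instance = sample_pattern_instance(spec.pattern, rng, probs)
                seqs[acc][start - 1:end] = list(instance)
                residue = "S" if rng.random() < 0.5 else "T"
                seqs[acc][site_pos - 1] = residue
                occupied[acc].append((span_lo, span_hi))
                embedded.append(EmbeddedMotif(
                    accession=acc, motif_id=spec.motif_id, start=start, end=end,
                    site=SiteKey(acc, site_pos, residue), spacer=spacer,
                    spacer_class=spec.placement,
                ))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place motif {spec.motif_id!r} (spacer off sequence "
                    "end after 200 attempts); enlarge proteins or reduce count"
                )

    sequences = {a: "".join(s) for a, s in seqs.items()}

    dis = config.disorder
    disorder: dict[str, np.ndarray] = {}
    for acc in accs:
        n = len(sequences[acc])
        track = dis.base_level + _smooth_noise(n, dis.noise_amplitude, rng)
        disorder[acc] = track
    for em in embedded:
        lo_i = max(0, em.start - 1 - dis.flank_pad)
        hi_i = min(len(sequences[em.accession]), em.end + dis.flank_pad)
        n = hi_i - lo_i
        disorder[em.accession][lo_i:hi_i] = (
            dis.motif_level + _smooth_noise(n, dis.noise_amplitude, rng)
        )
    for acc in accs:
        disorder[acc] = np.clip(disorder[acc], 0.0, 1.0)

    return Proteome(sequences=sequences, disorder=disorder, embedded=embedded)


def _pick_sites(config: SimulationConfig, proteome: Proteome,
                rng: np.random.Generator) -> list[SiteKey]:
    residues = "STY" if config.allow_tyrosine else "ST"
    forced = [em.site for em in proteome.embedded]
    blocked = set(forced)
    for em in proteome.embedded:  # keep random sites off embedded motif spans
        blocked.update(
            SiteKey(em.accession, p, proteome.sequences[em.accession][p - 1])
            for p in range(em.start, em.end + 1)
        )
    candidates = [
        SiteKey(acc, pos + 1, aa)
        for acc, seq in proteome.sequences.items()
        for pos, aa in enumerate(seq)
        if aa in residues
    ]
    candidates = [k for k in candidates if k not in blocked]
    n_extra = config.n_sites - len(forced)
    if n_extra < 0:
        raise ValueError(
            f"n_sites={config.n_sites} smaller than number of embedded sites ({len(forced)})"
        )
    if n_extra > len(candidates):
        raise ValueError(
            f"proteome offers only {len(candidates)} free S/T positions, "
            f"need {n_extra}; enlarge the proteome"
        )
    idx = rng.choice(len(candidates), size=n_extra, replace=False)
    return forced + [candidates[i] for i in sorted(idx)]


def _sensitive_sets(config: SimulationConfig, keys: list[SiteKey],
                    proteome: Proteome, rng: np.random.Generator
                    ) -> dict[str, dict[SiteKey, float]]:
    n = len(keys)
    out: dict[str, dict[SiteKey, float]] = {}
    # resolve inheritance in declaration order; parents must precede children
    for cond, eff in config.effects.items():
        if eff.sites_from is not None:
            parent = out.get(eff.sites_from)
            if parent is None:
                raise ValueError(
                    f"effect for {cond!r}: parent {eff.sites_from!r} must be "
                    "declared before it"
                )
            pool = list(parent)
            k = int(round(eff.fraction_of_inherited * len(pool)))
            idx = rng.choice(len(pool), size=k, replace=False) if k else []
            chosen = [pool[i] for i in sorted(idx)]
        else:
            if config.exact_fraction:
                k = int(round(eff.fraction_sensitive * n))
            else:
                k = int(rng.binomial(n, eff.fraction_sensitive))
            forced = (
                [em.site for em in proteome.embedded]
                if config.embedded_sites_sensitive else []
            )
            forced = forced[:k]
            rest_pool = [s for s in keys if s not in set(forced)]
            idx = rng.choice(len(rest_pool), size=k - len(forced), replace=False)
            chosen = forced + [rest_pool[i] for i in sorted(idx)]
        effects = eff.log2_effect_mean + eff.log2_effect_sd * rng.standard_normal(len(chosen))
        out[cond] = {s: float(e) for s, e in zip(chosen, effects)}
    return out


def generate_phospho_dataset(config: SimulationConfig, proteome: Proteome
                             ) -> tuple[PhosphoSiteTable, SyntheticTruth]:
    """Simulate the site-by-sample log2 intensity table plus its truth record.

    Baselines are Normal(baseline_mean, baseline_sd) per site; sensitive
    sites add their condition effect; replicates add Normal(0, replicate_sd)
    noise. Missingness acts on the pre-noise cell value (MNAR logistic) plus
    an MCAR coin flip. Embedded paired sites always get a localization
    probability >= 0.75 so motif-recovery truth survives the filter.
    """
    rng = np.random.default_rng([config.seed, 202])
    keys = _pick_sites(config, proteome, rng)
    n = len(keys)
    embedded_set = {em.site for em in proteome.embedded}

    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    sensitive = _sensitive_sets(config, keys, proteome, rng)

    samples = [
        f"{c.label}_{r}" for c in config.conditions for r in range(1, c.n_replicates + 1)
    ]
    design = pd.DataFrame(
        {
            "condition": [c.label for c in config.conditions
                          for _ in range(c.n_replicates)],
            "replicate": [r for c in config.conditions
                          for r in range(1, c.n_replicates + 1)],
        },
        index=pd.Index(samples, name="sample"),
    )

    values = np.empty((n, len(samples)))
    mech = np.full((n, len(samples)), "observed", dtype=object)
    col = 0
    for c in config.conditions:
        eff = np.zeros(n)
        cond_sens = sensitive.get(c.label, {})
        if cond_sens:
            lookup = {k: i for i, k in enumerate(keys)}
            for s, e in cond_sens.items():
                eff[lookup[s]] = e
        true_cell = baseline + eff  # pre-noise value, one per site for this condition
        p_mnar = config.missingness.p_mnar(true_cell)
        for _r in range(c.n_replicates):
            obs = true_cell + config.replicate_sd * rng.standard_normal(n)
            is_mnar = rng.random(n) < p_mnar
            is_mcar = rng.random(n) < config.missingness.mcar_rate
            obs[is_mnar | is_mcar] = np.nan
            values[:, col] = obs
            mech[is_mcar, col] = "mcar"
            mech[is_mnar, col] = "mnar"  # mnar label wins when both fire
            col += 1

    loc = rng.uniform(0.75, 1.0, size=n)
    low = rng.random(n) < config.frac_low_localization
    low &= np.array([k not in embedded_set for k in keys])
    loc[low] = rng.uniform(0.40, 0.745, size=int(low.sum()))

    sites = pd.DataFrame(
        {
            "accession": [k.accession for k in keys],
            "position": [k.position for k in keys],
            "residue": [k.residue for k in keys],
            "localization_prob": loc,
            "multiplicity": 1,
        }
    )
    table = PhosphoSiteTable(
        sites=sites,
        values=pd.DataFrame(values, columns=samples),
        design=design,
    )
    truth = SyntheticTruth(
        sensitive=sensitive,
        mechanisms=pd.DataFrame(mech, columns=samples),
        embedded=list(proteome.embedded),
        baseline=pd.Series(baseline),
    )
    return table, truth


def simulate_study(config: SimulationConfig
                   ) -> tuple[Proteome, PhosphoSiteTable, SyntheticTruth]:
    """Generate proteome and intensity table in one call."""
    proteome = generate_proteome(config)
    table, truth = generate_phospho_dataset(config, proteome)
    return proteome, table, truth
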