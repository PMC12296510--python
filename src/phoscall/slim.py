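"""Short linear motif (SLiM) scanning with exact p-values.

Degenerate patterns such as the B56-binding ``[LMFI]xx[IVL]x[ED]`` docking
motif are compiled to log2-odds weight matrices against a background
amino-acid model. Every sequence window is scored as the sum of
per-position weights, and the p-value — the probability that a random
background window scores at least as high — is computed exactly by dynamic
programming over the discretized score distribution, as motif scanners in
the MEME tradition do. Hits are then classified relative to called
phosphosites by spacer geometry (overlapping / upstream / downstream with
per-family minimum distances) and by mean intrinsic disorder over the
motif span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import SiteKey

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_GRANULARITY = 1e-3  # bits; DP rounding step for score discretization


def parse_pattern(pattern: str, alphabet: str = AA_ALPHABET) -> list[frozenset[str]]:
    """Parse a degenerate pattern into per-position letter sets.

    Supports single letters, bracketed sets like ``[LMFI]`` and the ``x``
    (or ``X``) wildcard meaning "any letter".
    """
    positions: list[frozenset[str]] = []
    i = 0
    allowed = set(alphabet)
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"pattern {pattern!r}: unclosed '['")
            members = pattern[i + 1:j]
            if not members:
                raise ValueError(f"pattern {pattern!r}: empty bracket set")
            bad = set(members) - allowed
            if bad:
                raise ValueError(f"pattern {pattern!r}: unknown letters {sorted(bad)}")
            positions.append(frozenset(members))
            i = j + 1
        elif ch in ("x", "X"):
            positions.append(frozenset(alphabet))
            i += 1
        elif ch in allowed:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"pattern {pattern!r}: unknown letter {ch!r}")
    if not positions:
        raise ValueError("empty pattern")
    return positions


def sample_pattern_instance(pattern: str, rng: np.random.Generator,
                            background: np.ndarray | None = None) -> str:
    """Draw one concrete sequence matching a degenerate pattern.

    Constrained positions are sampled uniformly within their set; wildcard
    positions are sampled from the background distribution.
    """
    positions = parse_pattern(pattern)
    if background is None:
        background = np.full(20, 1 / 20)
    letters = np.array(list(AA_ALPHABET))
    out = []
    for members in positions:
        if len(members) == len(AA_ALPHABET):
            out.append(str(rng.choice(letters, p=background)))
        else:
            ms = sorted(members)
            out.append(ms[int(rng.integers(len(ms)))])
    return "".join(out)


@dataclass
class MotifModel:
    """A compiled motif: per-position log2-odds weights and the exact score
    distribution needed for p-values.

    ``weights`` is L x 20 in bits; ``int_weights`` are the weights rounded
    to ``granularity`` used both for scoring and for the DP p-value table,
    so lookup p-values are exact for the discretized score.
    """

    id: str
    probs: np.ndarray  # L x 20 per-position probabilities (pseudocounted)
    background: np.ndarray  # length-20, sums to 1
    weights: np.ndarray  # L x 20 log2-odds in bits
    granularity: float = DEFAULT_GRANULARITY
    p_threshold: float = DEFAULT_P_THRESHOLD
    int_weights: np.ndarray = field(init=False)
    _sf: np.ndarray = field(init=False, repr=False)  # survival of int score
    _min_int: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._build_tables()

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def _build_tables(self) -> None:
        g = self.granularity
        for _ in range(8):
            iw = np.round(self.weights / g).astype(np.int64)
            span = int(iw.max(axis=1).sum() - iw.min(axis=1).sum()) + 1
            if span >= 100:
                break
            log.warning(
                "motif %s: score table has %d bins at granularity %g; refining",
                self.id, span, g,
            )
            g /= 10.0
        self.granularity = g
        self.int_weights = iw
        # DP: convolve per-position pmfs of the integer score under background
        pmf = np.array([1.0])
        offset = 0  # integer score corresponding to pmf[0]
        for pos in range(self.length):
            w = self.int_weights[pos]
            lo, hi = int(w.min()), int(w.max())
            step = np.zeros(hi - lo + 1)
            for aa_i, wi in enumerate(w):
                step[wi - lo] += self.background[aa_i]
            pmf = np.convolve(pmf, step)
            offset += lo
        sf = np.cumsum(pmf[::-1])[::-1]  # P(S >= s) for s = offset + index
        self._sf = np.minimum(sf, 1.0)
        self._min_int = offset

    def int_score(self, window: str) -> int | None:
        """Discretized score of one L-mer; None if a letter is non-standard."""
        total = 0
        for pos, ch in enumerate(window):
            idx = AA_INDEX.get(ch)
            if idx is None:
                return None
            total += int(self.int_weights[pos, idx])
        return total

    def pvalue_of_int_score(self, s: int) -> float:
        """Exact P(random background window scores >= s) on the DP grid."""
        i = s - self._min_int
        if i < 0:
            return 1.0
        if i >= len(self._sf):
            return 0.0
        return float(self._sf[i])

    @property
    def max_int_score(self) -> int:
        return int(self.int_weights.max(axis=1).sum())


def compile_motif(motif_id: str,
                  spec: str | np.ndarray,
                  background: np.ndarray | Mapping[str, float] | None = None,
                  pseudocount: float = 0.1,
                  granularity: float = DEFAULT_GRANULARITY,
                  p_threshold: float = DEFAULT_P_THRESHOLD) -> MotifModel:
    """Compile a degenerate pattern or explicit L x 20 probability matrix.

    Pattern positions become uniform probabilities within a bracketed set
    and background probabilities for the ``x`` wildcard. Probabilities are
    regularized as (p + pseudocount * background) / (1 + pseudocount) before
    the log2-odds transform, so absent letters stay finite.
    """
    if background is None:
        bg = np.full(20, 1 / 20)
    elif isinstance(background, Mapping):
        bg = np.array([background.get(a, 0.0) for a in AA_ALPHABET], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 20 frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("background frequencies must be strictly positive")

    if isinstance(spec, str):
        positions = parse_pattern(spec)
        probs = np.zeros((len(positions), 20))
        for i, members in enumerate(positions):
            if len(members) == 20:
                probs[i] = bg
            else:
                for m in members:
                    probs[i, AA_INDEX[m]] = 1.0 / len(members)
    else:
        probs = np.asarray(spec, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 20:
            raise ValueError("probability matrix must be L x 20")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability matrix rows must sum to 1")
    if probs.shape[0] < 3:
        raise ValueError(f"motif {motif_id!r}: length must be >= 3, got {probs.shape[0]}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (probs == 0).any():
        raise ValueError("pseudocount 0 with zero-probability cells gives -inf weights")

    reg = (probs + pseudocount * bg) / (1.0 + pseudocount)
    weights = np.log2(reg / bg)
    return MotifModel(id=motif_id, probs=reg, background=bg, weights=weights,
                      granularity=granularity, p_threshold=p_threshold)


HIT_COLUMNS = ["accession", "start", "end", "motif_id", "score", "p_value"]


def scan_sequence(model: MotifModel, accession: str, sequence: str,
                  p_threshold: float | None = None) -> pd.DataFrame:
    """Score every window of the model's length; emit hits with p <= threshold.

    Windows containing non-standard letters are skipped. Scores are in bits
    (discretized to the model granularity); hits are sorted by start.
    """
    thr = model.p_threshold if p_threshold is None else p_threshold
    L = model.length
    rows = []
    for start0 in range(len(sequence) - L + 1):
        window = sequence[start0:start0 + L]
        s = model.int_score(window)
        if s is None:
            continue
        p = model.pvalue_of_int_score(s)
        if p <= thr:
            rows.append({
                "accession": accession,
                "start": start0 + 1,
                "end": start0 + L,
                "motif_id": model.id,
                "score": s * model.granularity,
                "p_value": p,
            })
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def scan_proteome(models: Sequence[MotifModel], sequences: Mapping[str, str],
                  p_threshold: float | None = None) -> pd.DataFrame:
    frames = [
        f for f in (
            scan_sequence(m, acc, seq, p_threshold)
            for m in models for acc, seq in sequences.items()
        )
        if not f.empty
    ]
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# -- spacer and disorder classification -----------------------------------


@dataclass(frozen=True)
class SpacerRule:
    """Minimum separations for the upstream/downstream classes (residues)."""

    upstream_min: int = 10
    downstream_min: int = 20

    def __post_init__(self) -> None:
        if self.upstream_min < 1 or self.downstream_min < 1:
            raise ValueError("spacer thresholds must be >= 1")


CLASSIFIED_COLUMNS = HIT_COLUMNS + [
    "site_accession", "site_position", "site_residue", "spacer", "spacer_class"
]


def classify_hits(hits: pd.DataFrame, sites: Iterable[SiteKey],
                  rules: Mapping[str, SpacerRule] | SpacerRule | None = None
                  ) -> pd.DataFrame:
    """Pair every hit with every called site on the same protein and assign
    a spacer class.

    overlapping: site inside the motif span (spacer 0);
    upstream: motif end at least ``upstream_min`` residues before the site
    (spacer = site - end); downstream: motif start at least
    ``downstream_min`` residues after the site (spacer = start - site);
    anything closer but not overlapping is ``unassigned``.
    """
    if rules is None:
        rules = SpacerRule()
    sites_by_acc: dict[str, list[SiteKey]] = {}
    for s in sites:
        sites_by_acc.setdefault(s.accession, []).append(s)
    rows = []
    for hit in hits.itertuples(index=False):
        rule = (rules if isinstance(rules, SpacerRule)
                else rules.get(hit.motif_id, SpacerRule()))
        for s in sites_by_acc.get(hit.accession, []):
            if hit.start <= s.position <= hit.end:
                cls, spacer = "overlapping", 0
            elif hit.end <= s.position - rule.upstream_min:
                cls, spacer = "upstream", s.position - hit.end
            elif hit.start >= s.position + rule.downstream_min:
                cls, spacer = "downstream", hit.start - s.position
            else:
                cls = "unassigned"
                spacer = (s.position - hit.end if hit.end < s.position
                          else hit.start - s.position)
            rows.append(dict(
                **hit._asdict(),
                site_accession=s.accession, site_position=s.position,
                site_residue=s.residue, spacer=spacer, spacer_class=cls,
            ))
    return pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS)


def disorder_classify(hits: pd.DataFrame, tracks: Mapping[str, np.ndarray],
                      threshold: float = 0.5,
                      sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Flag each hit as disordered iff the mean per-residue disorder over its
    span is >= threshold (boundary inclusive)."""
    out = hits.copy()
    flags = []
    for hit in hits.itertuples(index=False):
        track = tracks.get(hit.accession)
        if track is None:
            raise KeyError(f"no disorder track for {hit.accession!r}")
        if sequences is not None and len(track) < len(sequences[hit.accession]):
            raise ValueError(
                f"disorder track for {hit.accession!r} shorter than protein "
                f"({len(track)} < {len(sequences[hit.accession])})"
            )
        if len(track) < hit.end:
            raise ValueError(
                f"disorder track for {hit.accession!r} shorter than hit end {hit.end}"
            )
        flags.append(bool(np.mean(track[hit.start - 1:hit.end]) >= threshold))
    out["disordered"] = flags
    return out


def spacer_distribution(classified: pd.DataFrame,
                        family_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-motif-family spacer summary for assigned (non-overlapping) pairs.

    Reports n, mean, sd (missing for n < 2), quartiles, skewness and excess
    kurtosis — the shape statistics, with no normality verdict.
    """
    df = classified[classified["spacer_class"].isin(["upstream", "downstream"])].copy()
    if family_of:
        df["family"] = df["motif_id"].map(lambda m: family_of.get(m, m))
    else:
        df["family"] = df["motif_id"]
    rows = []
    for fam, grp in df.groupby("family", sort=True):
        sp = grp["spacer"].to_numpy(dtype=float)
        rows.append({
            "family": fam,
            "n": len(sp),
            "mean": float(np.mean(sp)),
            "sd": float(np.std(sp, ddof=1)) if len(sp) > 1 else np.nan,
            "q25": float(np.percentile(sp, 25)),
            "median": float(np.median(sp)),
            "q75": float(np.percentile(sp, 75)),
            "skewness": float(stats.skew(sp)) if len(sp) > 2 else np.nan,
            "excess_kurtosis": float(stats.kurtosis(sp)) if len(sp) > 3 else np.nan,
        })
    return pd.DataFrame(rows)


def spacer_histogram(classified: pd.DataFrame) -> pd.DataFrame:
    df = classified[classified["spacer_class"].isin(["upstream", "downstream"])]
    counts = df.groupby(["motif_id", "spacer"]).size().rename("count").reset_index()
    return counts


def count_slim_site_assignments(sites: Iterable[SiteKey], hits: pd.DataFrame,
                                family_of: Mapping[str, str],
                                families: tuple[str, str] = ("B55", "B56")
                                ) -> dict[str, int]:
    """Partition called sites by the SLiM families present on their protein.

    Returns site counts for proteins carrying only the first family, only
    the second, both, or neither; the categories are disjoint and sum to the
    number of input sites.
    """
    fam_a, fam_b = families
    fams_by_acc: dict[str, set[str]] = {}
    for hit in hits.itertuples(index=False):
        fam = family_of.get(hit.motif_id, hit.motif_id)
        fams_by_acc.setdefault(hit.accession, set()).add(fam)
    counts = {f"{fam_a}_only": 0, f"{fam_b}_only": 0, "both": 0, "none": 0}
    for s in sites:
        fams = fams_by_acc.get(s.accession, set())
        has_a, has_b = fam_a in fams, fam_b in fams
        if has_a and has_b:
            counts["both"] += 1
        elif has_a:
            counts[f"{fam_a}_only"] += 1
        elif has_b:
            counts[f"{fam_b}_only"] += 1
        else:
            counts["none"] += 1
    return counts


#: B56-binding LxxIxE-class docking motif per the B56 SLiM literature.
#: The B55 entries are PLACEHOLDER degenerate approximations — confirm
#: against the primary B55 motif publications before use on real data.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "B56": "[LMFI]xx[IVL]x[ED]",
    "B55b": "[RK]x[VI]xx[VI][RK]",
    "B55H": "[ILV]x[ILV]xx[ILV][ED][ED]",
    "B55H2": "[KR][VI]x[VI]xx[KR]",
}

DEFAULT_FAMILY_OF: dict[str, str] = {
    "B56": "B56", "B55b": "B55", "B55H": "B55", "B55H2": "B55",
}
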