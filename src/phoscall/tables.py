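"""Core containers for phosphosite quantification data.

A phosphosite is identified by ``(accession, position, residue)`` with a
1-based residue index on the protein sequence, matching the conventional
"RPS6 Ser235" style of naming. Intensity matrices are kept on the log2
scale with ``NaN`` as the missing marker throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

ALLOWED_RESIDUES = frozenset({"S", "T", "Y"})

#: metadata columns every site table carries, in canonical order
SITE_COLUMNS = ["accession", "position", "residue", "localization_prob", "multiplicity"]


class SiteKey(NamedTuple):
    """Identity of a phosphosite: protein accession, 1-based position, residue."""

    accession: str
    position: int
    residue: str

    def __str__(self) -> str:  # e.g. "P62753:S235"
        return f"{self.accession}:{self.residue}{self.position}"


def validate_site_key(key: SiteKey) -> None:
    if key.position < 1:
        raise ValueError(f"site position must be >= 1, got {key.position} for {key}")
    if key.residue not in ALLOWED_RESIDUES:
        raise ValueError(
            f"unknown residue {key.residue!r} for {key.accession} position "
            f"{key.position}; expected one of {sorted(ALLOWED_RESIDUES)}"
        )


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison: ``group_a`` vs ``group_b`` condition labels.

    The fold change convention is mean(group_a) - mean(group_b) on the log2
    scale, so dephosphorylation in group_a appears as a negative value.
    """

    name: str
    group_a: str
    group_b: str
    direction: str = "two_sided"  # down_in_a | up_in_a | two_sided

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError(f"contrast {self.name!r}: group_a == group_b ({self.group_a!r})")
        if self.direction not in {"down_in_a", "up_in_a", "two_sided"}:
            raise ValueError(f"contrast {self.name!r}: unknown direction {self.direction!r}")


@dataclass
class PhosphoSiteTable:
    """Site-by-sample log2 intensity matrix with site metadata and design.

    Attributes
    ----------
    sites
        One row per quantified site; columns ``accession``, ``position``,
        ``residue``, ``localization_prob``, ``multiplicity``.
    values
        Log2 intensities, same row index as ``sites``, one column per
        sample; ``NaN`` marks a missing value.
    design
        Indexed by sample name; columns ``condition`` and ``replicate``.
    """

    sites: pd.DataFrame
    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table missing required columns: {missing_cols}")
        if len(self.sites) != len(self.values):
            raise ValueError(
                f"sites ({len(self.sites)}) and values ({len(self.values)}) row counts differ"
            )
        if not self.sites.index.equals(self.values.index):
            raise ValueError("sites and values indexes differ")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError(
                "value columns and design samples differ: "
                f"{list(self.values.columns)} vs {list(self.design.index)}"
            )
        if {"condition", "replicate"} - set(self.design.columns):
            raise ValueError("design needs 'condition' and 'replicate' columns")

        probs = self.sites["localization_prob"].to_numpy(dtype=float)
        ok = np.isnan(probs) | ((probs >= 0.0) & (probs <= 1.0))
        if not ok.all():
            bad = self.sites.index[~ok][:5].tolist()
            raise ValueError(f"localization probabilities outside [0,1] at rows {bad}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (inf) intensity values present")
        if (self.sites["position"].to_numpy() < 1).any():
            raise ValueError("site positions must be >= 1")
        bad_res = set(self.sites["residue"]) - ALLOWED_RESIDUES
        if bad_res:
            raise ValueError(f"unknown residue letters: {sorted(bad_res)}")

        dup = self.sites.duplicated(subset=["accession", "position", "residue", "multiplicity"])
        if dup.any():
            first = self.sites.loc[dup.idxmax()]
            raise ValueError(
                "duplicate site rows, first duplicate key: "
                f"({first['accession']}, {first['position']}, {first['residue']}) "
                f"multiplicity {first['multiplicity']}"
            )

    # -- accessors --------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        hit = self.design.index[self.design["condition"] == condition].tolist()
        if not hit:
            raise KeyError(f"condition {condition!r} not in design ({self.conditions})")
        return hit

    def site_keys(self) -> list[SiteKey]:
        return [
            SiteKey(a, int(p), r)
            for a, p, r in zip(
                self.sites["accession"], self.sites["position"], self.sites["residue"]
            )
        ]

    def subset(self, mask: Iterable[bool]) -> "PhosphoSiteTable":
        mask = np.asarray(list(mask), dtype=bool)
        return PhosphoSiteTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            values=self.values.loc[mask].reset_index(drop=True),
            design=self.design.copy(),
        )

    def copy(self) -> "PhosphoSiteTable":
        return PhosphoSiteTable(self.sites.copy(), self.values.copy(), self.design.copy())


def design_from_sample_names(samples: Iterable[str]) -> pd.DataFrame:
    """Infer a design from the ``condition_replicate`` naming convention.

    The replicate index is the token after the final underscore and must be
    an integer; everything before it is the condition label. Ambiguous names
    are an error rather than a guess.
    """
    rows = []
    for name in samples:
        if "_" not in name:
            raise ValueError(
                f"sample name {name!r} does not follow the 'condition_replicate' "
                "convention and no explicit design was given"
            )
        condition, _, rep = name.rpartition("_")
        if not rep.isdigit():
            raise ValueError(
                f"sample name {name!r}: token after final underscore ({rep!r}) "
                "is not an integer replicate index"
            )
        rows.append({"sample": name, "condition": condition, "replicate": int(rep)})
    design = pd.DataFrame(rows).set_index("sample")
    counts = design.groupby("condition").size()
    if (counts < 1).any():  # unreachable, kept for symmetry with validation
        raise ValueError("every condition needs at least one replicate")
    return design
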