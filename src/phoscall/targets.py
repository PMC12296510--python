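"""Set algebra over sensitivity calls: bona fide targets and Venn counts.

A bona fide phosphatase target site is one called sensitive (and
inhibitor-protected) in vitro AND regulated in vivo by both inhibitors —
the intersection of the per-experiment call sets. Sites intersect on exact
``(accession, position, residue)`` identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables import SiteKey


@dataclass(frozen=True)
class TargetCallSet:
    """A named set of site keys with the contrasts that produced it."""

    name: str
    sites: frozenset[SiteKey]
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"target set {self.name!r}: provenance must be non-empty")

    def __len__(self) -> int:
        return len(self.sites)


def set_from_calls(name: str, calls: pd.DataFrame, flag: str = "is_sensitive",
                   provenance: Sequence[str] | None = None) -> TargetCallSet:
    """Build a TargetCallSet from a calls frame (one row per site)."""
    sel = calls[calls[flag]]
    sites = frozenset(
        SiteKey(a, int(p), r)
        for a, p, r in zip(sel["accession"], sel["position"], sel["residue"])
    )
    return TargetCallSet(name=name, sites=sites,
                         provenance=tuple(provenance or (name,)))


def collapse_multiplicity(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiply-phosphorylated variants to one row per site key,
    keeping the most significant variant (smallest primary q)."""
    order = calls.sort_values("q_primary", kind="mergesort", na_position="last")
    return order.drop_duplicates(subset=["accession", "position", "residue"],
                                 keep="first").reset_index(drop=True)


def intersect_calls(sets: Sequence[TargetCallSet],
                    name: str = "intersection"
                    ) -> tuple[TargetCallSet, dict[str, int]]:
    """Intersection of >= 2 site sets plus all 2^n - 1 Venn region counts.

    Region keys are '&'-joined member-set names (e.g. ``"oa&lb100"`` for
    elements in exactly those two sets); region counts partition the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names: {names}")

    inter = frozenset.intersection(*(s.sites for s in sets))
    union = frozenset.union(*(s.sites for s in sets))
    regions: dict[str, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            key = "&".join(names[i] for i in combo)
            regions[key] = 0
    for elem in union:
        member = tuple(i for i, s in enumerate(sets) if elem in s.sites)
        key = "&".join(names[i] for i in member)
        regions[key] += 1

    provenance = tuple(p for s in sets for p in s.provenance)
    return TargetCallSet(name=name, sites=inter, provenance=provenance), regions


def overlap_with_reference(calls: TargetCallSet,
                           reference: Iterable[SiteKey],
                           name: str = "reference") -> dict[str, int]:
    """Compare a call set against a user-supplied published site list.

    Returns shared/unique counts at both site and protein level.
    """
    ref = frozenset(reference)
    shared_sites = calls.sites & ref
    our_proteins = {s.accession for s in calls.sites}
    ref_proteins = {s.accession for s in ref}
    return {
        "shared_sites": len(shared_sites),
        "our_only_sites": len(calls.sites - ref),
        f"{name}_only_sites": len(ref - calls.sites),
        "shared_proteins": len(our_proteins & ref_proteins),
    }


def summarize_targets(targets: TargetCallSet,
                      proteome: Mapping[str, str] | None = None
                      ) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-protein site counts and the sites-per-protein distribution.

    With a proteome given, sites whose accession is absent are counted as
    unmapped (``mapped`` False) but still summarized.
    """
    rows: dict[str, list[SiteKey]] = {}
    for s in sorted(targets.sites):
        rows.setdefault(s.accession, []).append(s)
    table = pd.DataFrame(
        [
            {
                "accession": acc,
                "n_sites": len(sites),
                "sites": ";".join(f"{k.residue}{k.position}" for k in sites),
                "mapped": (proteome is None) or (acc in proteome),
            }
            for acc, sites in sorted(rows.items())
        ],
        columns=["accession", "n_sites", "sites", "mapped"],
    )
    distribution: dict[int, int] = {}
    for n in table["n_sites"]:
        distribution[int(n)] = distribution.get(int(n), 0) + 1
    return table, distribution
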