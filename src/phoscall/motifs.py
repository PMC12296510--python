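"""Phosphosite-centered sequence windows, logo and preference matrices.

Windows span positions -flank..+flank around the phosphorylated residue
(default flank 7, i.e. 15-mers) and are padded with ``_`` where they
overrun a protein terminus. The position probability matrix (PPM) gives
per-position amino-acid frequencies for logo rendering; the preference
matrix contrasts strongly dephosphorylated sites (linear fold change >= 3)
against unchanged sites (|log2 fold change| <= 0.5) as a position-wise
log2 frequency ratio, masking cells where either set's count fraction
falls below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import SiteKey

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
PAD = "_"


@dataclass(frozen=True)
class SequenceWindow:
    site: SiteKey
    window: str  # length 2*flank+1, PAD outside sequence bounds

    @property
    def flank(self) -> int:
        return (len(self.window) - 1) // 2


def extract_windows(sites: Iterable[SiteKey], proteome: Mapping[str, str],
                    flank: int = 7) -> list[SequenceWindow]:
    """Cut the +/-flank window around each site, padding at termini.

    The window center must equal the annotated residue — a mismatch is a
    hard error, since it indicates a coordinate or annotation bug.
    """
    out = []
    for site in sites:
        seq = proteome.get(site.accession)
        if seq is None:
            raise KeyError(f"accession {site.accession!r} not in proteome")
        if not 1 <= site.position <= len(seq):
            raise ValueError(
                f"site {site} position out of bounds (protein length {len(seq)})"
            )
        center = seq[site.position - 1]
        if center != site.residue:
            raise ValueError(
                f"center mismatch for {site}: annotation says {site.residue}, "
                f"sequence has {center}"
            )
        lo = site.position - 1 - flank
        hi = site.position + flank  # exclusive, 0-based
        chunk = seq[max(lo, 0):min(hi, len(seq))]
        window = (PAD * max(-lo, 0)) + chunk + (PAD * max(hi - len(seq), 0))
        out.append(SequenceWindow(site=site, window=window))
    return out


def _position_labels(flank: int) -> list[int]:
    return list(range(-flank, flank + 1))


def position_probability_matrix(windows: Sequence[SequenceWindow]) -> pd.DataFrame:
    """Per-position amino-acid frequencies (20 rows x 2*flank+1 columns).

    Pad and non-standard characters are excluded from the denominator, so
    each column of observed positions sums to 1; an all-pad position is
    returned as a NaN (masked) column.
    """
    if not windows:
        raise ValueError("need at least one window")
    flank = windows[0].flank
    width = 2 * flank + 1
    if any(len(w.window) != width for w in windows):
        raise ValueError("inconsistent window lengths")
    counts = np.zeros((20, width))
    for w in windows:
        for j, ch in enumerate(w.window):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx, j] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), np.nan)
    return pd.DataFrame(freqs, index=list(AA_ALPHABET),
                        columns=_position_labels(flank))


@dataclass
class PreferenceMatrix:
    """Position-wise log2 enrichment of amino acids in sensitive vs
    insensitive windows, with a low-count mask.

    ``values`` carries NaN in masked cells; ``mask`` is True where a cell is
    excluded because either set's count fraction is below the minimum.
    """

    values: pd.DataFrame  # 20 x positions, log2(freq_sensitive/freq_insensitive)
    mask: pd.DataFrame  # bool, same shape
    n_sensitive: int
    n_insensitive: int


def _counts(windows: Sequence[SequenceWindow], width: int) -> np.ndarray:
    counts = np.zeros((20, width))
    for w in windows:
        for j, ch in enumerate(w.window):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx, j] += 1
    return counts


def preference_matrix(sensitive_windows: Sequence[SequenceWindow],
                      insensitive_windows: Sequence[SequenceWindow],
                      min_count_frac: float = 0.01,
                      pseudocount: float = 0.0) -> PreferenceMatrix:
    """log2 frequency-ratio matrix between two window sets.

    Frequencies are per position over non-pad characters, optionally
    regularized by adding ``pseudocount`` to every count. A cell is masked
    when its count fraction in either set is below ``min_count_frac``
    (the low-count exclusion rule); masked cells are NaN.
    """
    if not sensitive_windows or not insensitive_windows:
        raise ValueError("both window sets must be non-empty")
    flank = sensitive_windows[0].flank
    if insensitive_windows[0].flank != flank:
        raise ValueError("window sets have different flanks")
    width = 2 * flank + 1
    cs = _counts(sensitive_windows, width)
    ci = _counts(insensitive_windows, width)
    ts = cs.sum(axis=0)
    ti = ci.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        fs = np.where(ts > 0, cs / np.where(ts > 0, ts, 1), np.nan)
        fi = np.where(ti > 0, ci / np.where(ti > 0, ti, 1), np.nan)
        mask = (fs < min_count_frac) | (fi < min_count_frac)
        mask |= np.isnan(fs) | np.isnan(fi)
        fs_r = (cs + pseudocount) / (ts + 20 * pseudocount)
        fi_r = (ci + pseudocount) / (ti + 20 * pseudocount)
        vals = np.log2(fs_r / fi_r)
    vals[mask] = np.nan
    labels = _position_labels(flank)
    return PreferenceMatrix(
        values=pd.DataFrame(vals, index=list(AA_ALPHABET), columns=labels),
        mask=pd.DataFrame(mask, index=list(AA_ALPHABET), columns=labels),
        n_sensitive=len(sensitive_windows),
        n_insensitive=len(insensitive_windows),
    )


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (amino_acid, position, value) view for TSV output."""
    long = matrix.reset_index(names="amino_acid").melt(
        id_vars="amino_acid", var_name="position", value_name="value"
    )
    long["position"] = long["position"].astype(int)
    return long.sort_values(["position", "amino_acid"]).reset_index(drop=True)
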