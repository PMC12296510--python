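"""Preprocessing of phosphosite intensity tables.

The chain, in fixed order: localization-probability filter (>= 0.75 keeps a
site), removal of implausibly low log2 values (cell-wise floor at 5), two-
tier missing-value imputation — iterative low-rank SVD completion within
each condition group for sites observed in at least two replicates of that
group, then per-column downshifted-normal draws on the merged table to
mimic low-abundance measurements — and, optionally, normalization of each
phosphosite to its source protein's abundance by log-ratio.

Observed values are never altered by either imputation tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PhosphoSiteTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationParams:
    """Imputation settings.

    ``downshift_shift`` and ``downshift_width`` are in units of the
    per-column standard deviation of the observed values: imputed draws come
    from Normal(mean_j - shift * sd_j, (width * sd_j)^2). Defaults 1.8 / 0.3
    are the conventional downshift settings of mainstream proteomics
    quantification software.
    """

    min_valid_replicates: int = 2
    svd_rank: int = 2
    svd_tol: float = 1e-6
    svd_max_iter: int = 100
    downshift_width: float = 0.3
    downshift_shift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_valid_replicates < 2:
            raise ValueError("min_valid_replicates must be >= 2")
        if self.svd_rank < 1 or self.svd_tol <= 0 or self.svd_max_iter < 1:
            raise ValueError("svd_rank, svd_tol, svd_max_iter must be positive")
        if self.downshift_width <= 0 or self.downshift_shift <= 0:
            raise ValueError("downshift width and shift must be > 0")


def filter_localization(table: PhosphoSiteTable, min_prob: float = 0.75
                        ) -> PhosphoSiteTable:
    """Keep sites with localization probability >= min_prob (inclusive)."""
    keep = table.sites["localization_prob"].to_numpy(dtype=float) >= min_prob
    log.info("localization filter: removed %d of %d sites (< %.2f)",
             int((~keep).sum()), len(keep), min_prob)
    return table.subset(keep)


def floor_filter(table: PhosphoSiteTable, floor_log2: float = 5.0
                 ) -> PhosphoSiteTable:
    """Set individual cells below the log2 floor to missing (cell-wise)."""
    out = table.copy()
    vals = out.values.to_numpy(dtype=float)
    below = vals < floor_log2  # strict: exactly-at-floor values are kept
    log.info("floor filter: removed %d cells below %.3g", int(np.nansum(below)),
             floor_log2)
    vals[below] = np.nan
    out.values = pd.DataFrame(vals, columns=table.values.columns,
                              index=table.values.index)
    return out


def _complete_low_rank(x: np.ndarray, rank: int, tol: float, max_iter: int
                       ) -> np.ndarray:
    """Iterative rank-``rank`` completion: init missing at row means, then
    alternate truncated SVD reconstruction and missing-cell refresh."""
    mask = np.isnan(x)
    filled = x.copy()
    row_means = np.nanmean(np.where(mask, np.nan, x), axis=1)
    grand = np.nanmean(x)
    row_means = np.where(np.isnan(row_means), grand, row_means)
    filled[mask] = np.broadcast_to(row_means[:, None], x.shape)[mask]
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
        delta = np.abs(approx[mask] - filled[mask]).max(initial=0.0)
        filled[mask] = approx[mask]
        if delta < tol:
            break
    return filled


def impute_svd(table: PhosphoSiteTable, params: ImputationParams
               ) -> PhosphoSiteTable:
    """Low-rank SVD completion within each condition group.

    A site x condition block is eligible when the site has at least
    ``min_valid_replicates`` observed values in that condition; ineligible
    cells are left missing for the downshift tier. Observed cells are
    returned bit-identical.
    """
    out = table.copy()
    for cond in table.conditions:
        cols = table.condition_samples(cond)
        block = out.values[cols].to_numpy(dtype=float)
        if params.svd_rank >= min(block.shape):
            raise ValueError(
                f"svd_rank={params.svd_rank} must be < min matrix dimension "
                f"{min(block.shape)} for condition {cond!r}"
            )
        n_obs = (~np.isnan(block)).sum(axis=1)
        eligible = (n_obs >= params.min_valid_replicates) & (n_obs < block.shape[1])
        if not eligible.any():
            continue
        sub = block[eligible]
        completed = _complete_low_rank(sub, params.svd_rank, params.svd_tol,
                                       params.svd_max_iter)
        # only fill cells that were missing; observed stay untouched
        missing = np.isnan(sub)
        sub[missing] = completed[missing]
        block[eligible] = sub
        out.values.loc[:, cols] = block
        log.info("SVD imputation (%s): filled %d cells in %d eligible sites",
                 cond, int(missing.sum()), int(eligible.sum()))
    return out


def impute_downshift(table: PhosphoSiteTable, params: ImputationParams
                     ) -> PhosphoSiteTable:
    """Replace all remaining missing cells with per-column downshifted draws.

    Column j's draws come from Normal(mean_j - shift * sd_j, (width * sd_j)^2)
    with moments computed from that column's observed cells. Deterministic
    given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    out = table.copy()
    vals = out.values.to_numpy(dtype=float)
    for j, col in enumerate(out.values.columns):
        column = vals[:, j]
        obs = column[~np.isnan(column)]
        n_missing = int(np.isnan(column).sum())
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise ValueError(
                f"column {col!r} has only {len(obs)} observed values; "
                "cannot estimate a stable mean/SD for downshift imputation"
            )
        mean_j = float(np.mean(obs))
        sd_j = float(np.std(obs, ddof=1))
        draws = rng.normal(mean_j - params.downshift_shift * sd_j,
                           params.downshift_width * sd_j, size=n_missing)
        column[np.isnan(column)] = draws
        vals[:, j] = column
    out.values = pd.DataFrame(vals, columns=out.values.columns,
                              index=out.values.index)
    return out


def normalize_to_protein(phospho: PhosphoSiteTable, protein: pd.DataFrame
                         ) -> tuple[PhosphoSiteTable, pd.DataFrame]:
    """Normalize each site to its source protein by log2 ratio.

    ``protein`` is an accession-indexed log2 abundance frame whose columns
    must cover the phospho samples. Sites whose accession lacks a complete
    protein profile are dropped from the normalized table and returned in
    the report with the reason.
    """
    missing_samples = [s for s in phospho.samples if s not in protein.columns]
    if missing_samples:
        raise ValueError(
            f"protein table lacks sample column(s) {missing_samples}"
        )
    prot = protein[phospho.samples]
    report_rows = []
    keep = np.ones(len(phospho.sites), dtype=bool)
    vals = phospho.values.to_numpy(dtype=float).copy()
    for i, acc in enumerate(phospho.sites["accession"]):
        if acc not in prot.index:
            keep[i] = False
            report_rows.append({"accession": acc, "reason": "no_protein_quant"})
            continue
        prow = prot.loc[acc].to_numpy(dtype=float)
        if np.isnan(prow).any():
            keep[i] = False
            report_rows.append({"accession": acc, "reason": "incomplete_protein_profile"})
            continue
        vals[i] = vals[i] - prow
    out = PhosphoSiteTable(
        sites=phospho.sites.copy(),
        values=pd.DataFrame(vals, columns=phospho.values.columns,
                            index=phospho.values.index),
        design=phospho.design.copy(),
    ).subset(keep)
    report = pd.DataFrame(report_rows, columns=["accession", "reason"])
    log.info("protein normalization: %d of %d sites normalizable",
             int(keep.sum()), len(keep))
    return out, report


def preprocess_pipeline(table: PhosphoSiteTable,
                        params: ImputationParams | None = None,
                        min_localization: float = 0.75,
                        floor_log2: float = 5.0,
                        protein: pd.DataFrame | None = None
                        ) -> PhosphoSiteTable:
    """Run the fixed-order chain: localization -> floor -> per-condition SVD
    -> merged downshift -> (optional) protein normalization."""
    params = params or ImputationParams()
    t = filter_localization(table, min_localization)
    t = floor_filter(t, floor_log2)
    t = impute_svd(t, params)
    t = impute_downshift(t, params)
    if protein is not None:
        t, _ = normalize_to_protein(t, protein)
    return t
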