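"""Two-sample testing, FDR control and phosphatase-sensitivity calls.

Each contrast is an unpaired Student's t test with pooled variance on the
log2 intensities; the fold change convention is mean(group_a) -
mean(group_b), so dephosphorylation by an added phosphatase appears as a
negative log2 fold change against the untreated control. Benjamini-
Hochberg is the default FDR procedure; a group-label permutation FDR with
an optional SAM-style s0 variance fudge is available as an alternative.

Sensitivity calling encodes the inhibitor-protection logic: a site is a
target candidate when it is dephosphorylated by the phosphatase relative to
control AND that dephosphorylation is blocked by the inhibitor (i.e., the
site is significantly lower in the phosphatase-only than in the
phosphatase-plus-inhibitor condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import ContrastSpec, PhosphoSiteTable

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "accession", "position", "residue", "multiplicity", "contrast",
    "log2fc", "t_stat", "p_value", "n_a", "n_b", "degenerate_variance",
]


@dataclass(frozen=True)
class CallPolicy:
    """Thresholds for categorical calls.

    ``strong_fc_threshold`` is a linear fold change (>= 3 means
    |log2fc| >= log2 3); ``insensitive_band`` is in log2 units.
    """

    q_threshold: float = 0.05
    insensitive_band: tuple[float, float] = (-0.5, 0.5)
    strong_fc_threshold: float = 3.0
    strong_fc_is_linear: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.insensitive_band
        if not (lo < 0 < hi):
            raise ValueError("insensitive_band must straddle 0")
        if self.strong_fc_threshold <= 1:
            raise ValueError("strong_fc_threshold must be > 1 (linear scale)")

    @property
    def strong_log2(self) -> float:
        if self.strong_fc_is_linear:
            return float(np.log2(self.strong_fc_threshold))
        return float(self.strong_fc_threshold)


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = (~np.isnan(values)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=1)
        var = np.full(len(values), np.nan)
        ok = n > 1
        if ok.any():
            var[ok] = np.nanvar(values[ok], axis=1, ddof=1)
    return n, mean, var


def ttest_contrast(table: PhosphoSiteTable, contrast: ContrastSpec,
                   s0: float = 0.0) -> pd.DataFrame:
    """Unpaired pooled-variance t test of group_a vs group_b per site.

    Degenerate variance convention: when the pooled variance is zero, p = 1
    if the group means are equal, otherwise p is set to the smallest
    positive float and the row is flagged ``degenerate_variance``. Sites
    with fewer than two observed values in either group get p = NaN
    (not testable). ``s0`` is an optional fudge added to the standard error
    (used by the permutation FDR mode); the default 0 is the plain t test.
    """
    a_cols = table.condition_samples(contrast.group_a)
    b_cols = table.condition_samples(contrast.group_b)
    a = table.values[a_cols].to_numpy(dtype=float)
    b = table.values[b_cols].to_numpy(dtype=float)
    na, ma, va = _group_stats(a)
    nb, mb, vb = _group_stats(b)

    lfc = ma - mb
    testable = (na >= 2) & (nb >= 2)
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb)) + s0
        t = lfc / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = testable & (sp2 == 0) & (s0 == 0)
    equal_means = degenerate & (lfc == 0)
    unequal = degenerate & (lfc != 0)
    t[equal_means] = 0.0
    p[equal_means] = 1.0
    p[unequal] = np.finfo(float).tiny
    t[unequal] = np.sign(lfc[unequal]) * np.inf
    p[~testable] = np.nan
    t[~testable] = np.nan

    out = table.sites[["accession", "position", "residue", "multiplicity"]].copy()
    out["contrast"] = contrast.name
    out["log2fc"] = lfc
    out["t_stat"] = t
    out["p_value"] = p
    out["n_a"] = na
    out["n_b"] = nb
    out["degenerate_variance"] = degenerate
    return out


def fdr_adjust(p_values, method: str = "bh", *,
               t_obs: np.ndarray | None = None,
               t_null: np.ndarray | None = None) -> np.ndarray:
    """One q-value per input p-value.

    ``bh`` is Benjamini-Hochberg step-up. ``permutation`` estimates, at each
    observed |t| threshold, FDR = mean null exceedance count / observed
    exceedance count; it requires ``t_obs`` (observed statistics, same order
    as p_values) and ``t_null`` (n_permutations x n_sites matrix from
    :func:`permutation_null`). NaN p-values pass through as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if method == "bh":
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return q
    if method != "permutation":
        raise ValueError(f"unknown FDR method {method!r}")
    if t_obs is None or t_null is None:
        raise ValueError("permutation FDR needs t_obs and t_null")
    t_abs = np.abs(np.asarray(t_obs, dtype=float))[ok]
    null_abs = np.sort(np.abs(np.asarray(t_null, dtype=float)).ravel())
    null_abs = null_abs[~np.isnan(null_abs)]
    n_perm = t_null.shape[0]
    obs_sorted = np.sort(t_abs)
    m = len(t_abs)
    qs = np.empty(m)
    for i, thr in enumerate(t_abs):
        n_null = len(null_abs) - np.searchsorted(null_abs, thr, side="left")
        n_obs = m - np.searchsorted(obs_sorted, thr, side="left")
        qs[i] = min(1.0, (n_null / n_perm) / max(n_obs, 1))
    # q_i = min FDR estimate over thresholds |t'| <= |t_i| (step-up, as BH):
    # accumulate the running minimum from the least significant site upward
    order = np.argsort(t_abs)
    qs[order] = np.minimum.accumulate(qs[order])
    q[ok] = qs
    return q


def permutation_null(table: PhosphoSiteTable, contrast: ContrastSpec,
                     n_permutations: int = 1000, s0: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Null t statistics from random group-label permutations.

    Returns an (n_permutations x n_sites) matrix; rows are t statistics of
    the same contrast after shuffling the pooled sample labels.
    """
    rng = np.random.default_rng(seed)
    a_cols = table.condition_samples(contrast.group_a)
    b_cols = table.condition_samples(contrast.group_b)
    pooled = table.values[a_cols + b_cols].to_numpy(dtype=float)
    na = len(a_cols)
    n_total = pooled.shape[1]
    out = np.empty((n_permutations, len(pooled)))
    for k in range(n_permutations):
        perm = rng.permutation(n_total)
        a = pooled[:, perm[:na]]
        b = pooled[:, perm[na:]]
        n1, m1, v1 = _group_stats(a)
        n2, m2, v2 = _group_stats(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)) + s0
            out[k] = (m1 - m2) / se
    return out


def run_contrasts(table: PhosphoSiteTable, contrasts: list[ContrastSpec],
                  fdr_method: str = "bh", n_permutations: int = 1000,
                  s0: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Test every contrast and attach q-values (FDR within each contrast)."""
    frames = []
    for c in contrasts:
        res = ttest_contrast(table, c, s0=s0 if fdr_method == "permutation" else 0.0)
        if fdr_method == "permutation":
            null = permutation_null(table, c, n_permutations, s0=s0, seed=seed)
            res["q_value"] = fdr_adjust(res["p_value"], "permutation",
                                        t_obs=res["t_stat"].to_numpy(),
                                        t_null=null)
        else:
            res["q_value"] = fdr_adjust(res["p_value"], "bh")
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def call_sensitivity(results: pd.DataFrame, policy: CallPolicy,
                     primary: str, protection: str | None = None,
                     direction: str = "down") -> pd.DataFrame:
    """Categorical per-site calls from per-contrast test results.

    ``primary`` names the contrast defining sensitivity (phosphatase vs
    control in vitro; inhibitor vs starved in vivo, with ``direction='up'``
    since inhibition preserves phosphorylation). ``protection`` names the
    phosphatase vs phosphatase-plus-inhibitor contrast; a sensitive site
    that is also significantly lower there is inhibitor-protected, i.e. a
    specific target candidate.
    """
    if direction not in {"down", "up"}:
        raise ValueError("direction must be 'down' or 'up'")
    have = set(results["contrast"])
    for name in [primary] + ([protection] if protection else []):
        if name not in have:
            raise ValueError(f"required contrast {name!r} missing from results")

    key_cols = ["accession", "position", "residue", "multiplicity"]
    prim = results[results["contrast"] == primary].set_index(key_cols)
    lfc = prim["log2fc"]
    q = prim["q_value"]
    sign_ok = (lfc < 0) if direction == "down" else (lfc > 0)
    sensitive = (q < policy.q_threshold) & sign_ok
    lo, hi = policy.insensitive_band
    insensitive = (lfc >= lo) & (lfc <= hi)
    strong = sensitive & (np.abs(lfc) >= policy.strong_log2)
    not_testable = q.isna()

    calls = pd.DataFrame({
        "log2fc_primary": lfc,
        "q_primary": q,
        "is_sensitive": sensitive.fillna(False),
        "is_insensitive": (insensitive & ~sensitive).fillna(False),
        "is_strong": strong.fillna(False),
        "not_testable": not_testable,
    })
    if protection is not None:
        prot = results[results["contrast"] == protection].set_index(key_cols)
        prot = prot.reindex(calls.index)
        blocked = (prot["q_value"] < policy.q_threshold) & (prot["log2fc"] < 0)
        calls["is_protected"] = (calls["is_sensitive"] & blocked).fillna(False)
    else:
        calls["is_protected"] = False

    def label(row) -> str:
        if row["not_testable"]:
            return "not_testable"
        if row["is_protected"]:
            return "protected_candidate"
        if row["is_sensitive"]:
            return "sensitive"
        if row["is_insensitive"]:
            return "insensitive"
        return "unchanged"

    calls["call"] = calls.apply(label, axis=1)
    return calls.reset_index()
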