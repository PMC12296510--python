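"""Filters, SVD completion and downshift imputation against closed forms."""

import numpy as np
import pandas as pd
import pytest

import phoscall as pc
from phoscall.preprocess import _complete_low_rank
from tests.conftest import make_table


def test_localization_filter_boundary_inclusive(six_sample_names):
    t = make_table(np.full((3, 6), 20.0), six_sample_names,
                   loc_probs=[0.9, 0.75, 0.74])
    out = pc.filter_localization(t, 0.75)
    assert len(out.sites) == 2
    assert pc.filter_localization(t, 0.0).sites.equals(t.sites)
    empty = pc.filter_localization(t, 0.99)
    assert len(empty.sites) == 0  # all below threshold: empty table, no error


def test_floor_filter_is_cell_wise_and_strict(six_sample_names):
    vals = np.full((2, 6), 20.0)
    vals[0, 0] = 4.9
    vals[0, 1] = 5.0
    vals[1, :] = 4.0  # whole row below floor: retained, fully missing
    out = pc.floor_filter(make_table(vals, six_sample_names), 5.0)
    assert np.isnan(out.values.iloc[0, 0])
    assert out.values.iloc[0, 1] == 5.0
    assert len(out.sites) == 2
    assert out.values.iloc[1].isna().all()
    # floor -inf is the identity
    ident = pc.floor_filter(make_table(vals, six_sample_names), -np.inf)
    assert np.allclose(ident.values.to_numpy(), vals)


def test_svd_completion_recovers_rank1_entry():
    x = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    x_masked = x.copy()
    x_masked[1, 1] = np.nan
    filled = _complete_low_rank(x_masked, rank=1, tol=1e-9, max_iter=200)
    assert abs(filled[1, 1] - 10.0) < 1e-6


def test_svd_completion_recovers_random_rank2_matrix():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 2)) @ rng.normal(size=(2, 6))
    mask = rng.random(x.shape) < 0.05
    x_masked = np.where(mask, np.nan, x)
    filled = _complete_low_rank(x_masked, rank=2, tol=1e-9, max_iter=500)
    err = np.abs(filled[mask] - x[mask])
    assert np.median(err) < 1e-3


def test_impute_svd_eligibility_and_observed_untouched(six_sample_names):
    rng = np.random.default_rng(1)
    base = rng.normal(25, 2, size=(50, 1))
    vals = base + rng.normal(0, 0.1, size=(50, 6))
    vals[0, 0] = np.nan            # 2 observed in ctrl -> eligible
    vals[1, 0] = vals[1, 1] = np.nan  # 1 observed in ctrl -> left missing
    t = make_table(vals, six_sample_names)
    out = pc.impute_svd(t, pc.ImputationParams())
    assert not np.isnan(out.values.iloc[0, 0])
    assert np.isnan(out.values.iloc[1, 0]) and np.isnan(out.values.iloc[1, 1])
    obs_mask = ~np.isnan(vals)
    assert np.array_equal(out.values.to_numpy()[obs_mask], vals[obs_mask])


def test_impute_svd_rank_too_large_is_error(small_table):
    with pytest.raises(ValueError, match="svd_rank"):
        pc.impute_svd(small_table, pc.ImputationParams(svd_rank=3))


def test_downshift_moments_match_closed_form(six_sample_names):
    """Column mean 25, sd 2, shift 1.8, width 0.3 -> draws ~ N(21.4, 0.6^2)."""
    rng = np.random.default_rng(2)
    n = 20000
    vals = np.empty((n, 6))
    vals[:, :] = rng.normal(25, 2, size=(n, 1))  # same per row across cols
    miss = rng.random(n) < 0.5
    col0 = vals[:, 0].copy()
    col0[miss] = np.nan
    # force exact observed moments in column 0 so the closed form is exact
    obs = col0[~np.isnan(col0)]
    col0[~np.isnan(col0)] = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
    vals[:, 0] = col0
    t = make_table(vals, six_sample_names)
    out = pc.impute_downshift(t, pc.ImputationParams(seed=5))
    draws = out.values.to_numpy()[miss, 0]
    assert len(draws) >= 9000
    assert abs(draws.mean() - 21.4) < 0.03
    assert abs(draws.std(ddof=1) - 0.6) < 0.03
    frac_below_mean = (draws < 25.0).mean()
    assert frac_below_mean >= 0.96


def test_downshift_identity_determinism_and_small_column(six_sample_names):
    vals = np.random.default_rng(3).normal(25, 2, size=(10, 6))
    t = make_table(vals, six_sample_names)
    out = pc.impute_downshift(t, pc.ImputationParams(seed=1))
    assert np.array_equal(out.values.to_numpy(), vals)  # no missing -> identity
    vals[0, 0] = np.nan
    t2 = make_table(vals, six_sample_names)
    a = pc.impute_downshift(t2, pc.ImputationParams(seed=1))
    b = pc.impute_downshift(t2, pc.ImputationParams(seed=1))
    assert a.values.equals(b.values)
    thin = make_table(np.array([[20, np.nan, np.nan, np.nan, 21, 22],
                                [np.nan, 20, np.nan, np.nan, 21, 22]]),
                      six_sample_names)
    with pytest.raises(ValueError, match="observed values"):
        pc.impute_downshift(thin, pc.ImputationParams())


def test_normalize_to_protein_log_ratio(six_sample_names):
    t = make_table(np.array([[20.0] * 6, [22.0] * 6]), six_sample_names,
                   accessions=["P1", "P2"])
    protein = pd.DataFrame([[18.0] * 6], index=["P1"],
                           columns=six_sample_names)
    out, report = pc.normalize_to_protein(t, protein)
    assert len(out.sites) == 1
    assert np.allclose(out.values.to_numpy(), 2.0)
    assert report.iloc[0]["accession"] == "P2"
    assert report.iloc[0]["reason"] == "no_protein_quant"
    with pytest.raises(ValueError, match="sample"):
        pc.normalize_to_protein(t, protein.rename(columns={"oa_3": "oops_3"}))


def test_protein_constant_preserves_fold_changes(six_sample_names):
    rng = np.random.default_rng(4)
    vals = rng.normal(22, 1, size=(5, 6))
    t = make_table(vals, six_sample_names, accessions=[f"P{i}" for i in range(5)])
    protein = pd.DataFrame(np.full((5, 6), 17.0), index=[f"P{i}" for i in range(5)],
                           columns=six_sample_names)
    out, _ = pc.normalize_to_protein(t, protein)
    raw_fc = vals[:, 3:].mean(axis=1) - vals[:, :3].mean(axis=1)
    norm = out.values.to_numpy()
    norm_fc = norm[:, 3:].mean(axis=1) - norm[:, :3].mean(axis=1)
    assert np.allclose(raw_fc, norm_fc, atol=1e-12)


def test_pipeline_is_noop_on_its_own_output(six_sample_names):
    rng = np.random.default_rng(6)
    vals = rng.normal(25, 2, size=(60, 6))
    vals[rng.random(vals.shape) < 0.1] = np.nan
    t = make_table(vals, six_sample_names)
    once = pc.preprocess_pipeline(t, pc.ImputationParams(seed=0))
    twice = pc.preprocess_pipeline(once, pc.ImputationParams(seed=0))
    assert once.values.equals(twice.values)
    assert once.sites.equals(twice.sites)


def test_effect_recovery_after_imputation_under_mnar():
    """Sites with at most one missing replicate per group keep their true
    effect within 0.25 on average after the two-tier imputation."""
    cfg = pc.SimulationConfig(
        n_proteins=30, protein_length_range=(300, 400), n_sites=500, seed=21,
        effects={"treated": pc.EffectSpec(0.2, -2.0, 0.5)},
    )
    _, table, truth = pc.simulate_study(cfg)
    pre = pc.preprocess_pipeline(table, pc.ImputationParams(seed=21))
    tcols = pre.condition_samples("treated")
    ccols = pre.condition_samples("control")
    obs_t = table.values[tcols].notna().sum(axis=1)
    obs_c = table.values[ccols].notna().sum(axis=1)
    raw_keys = table.site_keys()
    well = {k for i, k in enumerate(raw_keys)
            if obs_t[i] >= 2 and obs_c[i] >= 2}
    est = (pre.values[tcols].mean(axis=1) - pre.values[ccols].mean(axis=1))
    sens = truth.sensitive["treated"]
    errors = [est[i] - sens[k] for i, k in enumerate(pre.site_keys())
              if k in sens and k in well]
    assert len(errors) > 30
    assert abs(np.mean(errors)) < 0.25
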