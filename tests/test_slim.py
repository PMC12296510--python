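"""Motif compilation, exact DP p-values and hit classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phoscall as pc
from phoscall.slim import (AA_ALPHABET, AA_INDEX, DEFAULT_FAMILY_OF,
                           SpacerRule, parse_pattern, sample_pattern_instance)
from phoscall.tables import SiteKey

B56_PATTERN = "[LMFI]xx[IVL]x[ED]"


def test_pattern_parsing_and_validation():
    pos = parse_pattern(B56_PATTERN)
    assert len(pos) == 6
    assert pos[0] == frozenset("LMFI")
    assert len(pos[1]) == 20  # wildcard
    assert pos[5] == frozenset("ED")
    with pytest.raises(ValueError, match="unclosed"):
        parse_pattern("[LM")
    with pytest.raises(ValueError, match="unknown"):
        parse_pattern("AB1")
    with pytest.raises(ValueError, match="length must be >= 3"):
        pc.compile_motif("short", "[LM]")


def test_consensus_set_scores_equal_and_maximal():
    """All 4*3*2 = 24 consensus hexamers of the B56-class pattern share the
    maximal score under a uniform background."""
    model = pc.compile_motif("B56", B56_PATTERN)
    assert model.length == 6
    scores = set()
    for a, d, f in itertools.product("LMFI", "IVL", "ED"):
        s = model.int_score(a + "AA" + d + "A" + f)
        scores.add(s)
    assert len(scores) == 1
    assert scores.pop() == model.max_int_score
    # wildcard positions contribute zero weight: any letter there is equal
    assert model.int_score("LQQIQE") == model.max_int_score


def test_explicit_matrix_round_trips():
    model = pc.compile_motif("B56", B56_PATTERN)
    again = pc.compile_motif("B56", model.probs, pseudocount=0.0)
    assert np.allclose(model.weights, again.weights, atol=1e-12)


def test_dp_pvalues_match_exhaustive_enumeration():
    """Full 20^4 enumeration of a length-4 model: the DP survival function
    is exact at every achievable score."""
    model = pc.compile_motif("M4", "[LM]x[ED][KR]")
    w = model.int_weights
    scores = (w[0][:, None, None, None] + w[1][None, :, None, None]
              + w[2][None, None, :, None] + w[3][None, None, None, :]).ravel()
    # uniform background: every 4-mer has probability 20^-4
    order = np.argsort(scores)
    for s in np.unique(scores[::997]):  # spot-check a spread of scores
        brute = (scores >= s).mean()
        assert model.pvalue_of_int_score(int(s)) == pytest.approx(brute, abs=1e-12)
    assert model.pvalue_of_int_score(int(scores.max())) == pytest.approx(
        (scores == scores.max()).mean(), abs=1e-12)


def test_dp_pvalue_of_b56_consensus_equals_combinatorial_count():
    """P(score >= max) = (4*3*2 constrained combos) / 20^3 for the 3
    constrained positions; wildcards are free."""
    model = pc.compile_motif("B56", B56_PATTERN)
    expected = (4 * 3 * 2) / 20**3
    assert model.pvalue_of_int_score(model.max_int_score) == pytest.approx(
        expected, rel=1e-9)


def test_dp_pvalues_agree_with_monte_carlo():
    rng = np.random.default_rng(17)
    model = pc.compile_motif("B56", B56_PATTERN)
    n = 1_000_000
    draws = rng.integers(0, 20, size=(n, model.length))
    mc_scores = model.int_weights[np.arange(model.length), draws].sum(axis=1)
    # threshold near p ~ 1e-3
    thr = np.quantile(mc_scores, 1 - 1e-3)
    p_mc = (mc_scores >= thr).mean()
    p_dp = model.pvalue_of_int_score(int(np.ceil(thr)))
    se = np.sqrt(p_mc * (1 - p_mc) / n)
    assert abs(p_dp - p_mc) < 3 * se + 1e-9


def test_pvalue_monotone_in_score():
    model = pc.compile_motif("B56", B56_PATTERN)
    lo = model.int_weights.min(axis=1).sum()
    hi = model.max_int_score
    grid = np.linspace(lo, hi, 200).astype(int)
    ps = [model.pvalue_of_int_score(int(s)) for s in grid]
    assert all(a >= b for a, b in zip(ps[:-1], ps[1:]))


def test_scan_finds_planted_consensus_and_skips_low_scores():
    model = pc.compile_motif("B56x", "[LMFI]xx[IVL]x[ED]xx[ED][ED]")
    seq = "A" * 30 + "LQQIQEQQEE" + "A" * 30
    hits = pc.scan_sequence(model, "P1", seq)
    assert len(hits) == 1
    assert hits.loc[0, "start"] == 31 and hits.loc[0, "end"] == 40
    assert hits.loc[0, "p_value"] <= 1e-4
    none = pc.scan_sequence(model, "P2", "A" * 100)
    assert none.empty


def test_sampled_pattern_instances_match_pattern():
    rng = np.random.default_rng(18)
    positions = parse_pattern(B56_PATTERN)
    for _ in range(50):
        inst = sample_pattern_instance(B56_PATTERN, rng)
        assert all(ch in members for ch, members in zip(inst, positions))


def _hits_frame(rows):
    return pd.DataFrame(rows, columns=["accession", "start", "end", "motif_id",
                                       "score", "p_value"])


def test_spacer_classification_rules():
    sites = [SiteKey("P1", 40, "S")]
    hits = _hits_frame([
        ("P1", 20, 25, "B56", 5.0, 1e-5),   # end 25 <= 40-10 -> upstream, spacer 15
        ("P1", 38, 43, "B56", 5.0, 1e-5),   # site inside span -> overlapping
        ("P1", 55, 60, "B56", 5.0, 1e-5),   # start-site = 15 < 20 -> unassigned
        ("P1", 62, 67, "B56", 5.0, 1e-5),   # start-site = 22 >= 20 -> downstream
        ("P1", 33, 38, "B56", 5.0, 1e-5),   # end 38 > 30 -> unassigned (too close)
    ])
    out = pc.classify_hits(hits, sites, SpacerRule(10, 20))
    got = list(zip(out["spacer_class"], out["spacer"]))
    assert got[0] == ("upstream", 15)
    assert got[1] == ("overlapping", 0)
    assert got[2][0] == "unassigned"
    assert got[3] == ("downstream", 22)
    assert got[4][0] == "unassigned"
    # classes are mutually exclusive and exhaustive by construction
    assert set(out["spacer_class"]) <= {"overlapping", "upstream",
                                        "downstream", "unassigned"}


def test_spacer_rule_validation():
    with pytest.raises(ValueError, match=">= 1"):
        SpacerRule(0, 20)


def test_disorder_classification_boundary():
    hits = _hits_frame([("P1", 1, 6, "B56", 5.0, 1e-5)])
    classified = pc.classify_hits(hits, [SiteKey("P1", 30, "S")])
    for level, expect in ((1.0, True), (0.49, False), (0.5, True)):
        out = pc.disorder_classify(classified, {"P1": np.full(40, level)})
        assert out.loc[0, "disordered"] is np.True_ if expect else ~out.loc[0, "disordered"]
    mixed = np.array([0.4, 0.4, 0.8, 0.8, 0.8, 0.8])
    out = pc.disorder_classify(classified, {"P1": np.concatenate([mixed, np.zeros(34)])})
    assert out.loc[0, "disordered"]  # mean 0.633 >= 0.5
    with pytest.raises(ValueError, match="shorter"):
        pc.disorder_classify(classified, {"P1": np.full(3, 1.0)})


def test_spacer_distribution_summaries():
    sites = [SiteKey("P1", 100, "S")]
    hits = _hits_frame([("P1", 84, 90, "B56", 5.0, 1e-5),
                        ("P1", 82, 88, "B56", 5.0, 1e-5),
                        ("P1", 80, 86, "B56", 5.0, 1e-5)])
    out = pc.classify_hits(hits, sites, SpacerRule(10, 20))
    summary = pc.spacer_distribution(out, DEFAULT_FAMILY_OF)
    row = summary.set_index("family").loc["B56"]
    assert row["n"] == 3
    assert row["mean"] == pytest.approx(12.0)
    assert row["sd"] == pytest.approx(2.0)
    # single observation: sd reported missing
    single = pc.classify_hits(hits.iloc[:1], sites, SpacerRule(10, 20))
    s = pc.spacer_distribution(single).iloc[0]
    assert np.isnan(s["sd"])


def test_spacer_sample_mean_clt_bound():
    rng = np.random.default_rng(19)
    spacers = np.round(rng.normal(30, 5, size=500)).astype(int)
    hits = _hits_frame([("P1", 200 + 30 * i, 205 + 30 * i, "B56", 5.0, 1e-5)
                        for i in range(500)])
    classified = hits.assign(site_accession="P1", site_position=1,
                             site_residue="S", spacer=spacers,
                             spacer_class="downstream")
    summary = pc.spacer_distribution(classified)
    assert abs(summary.iloc[0]["mean"] - 30) < 0.7


def test_slim_family_site_partition_counts():
    sites = [SiteKey("P1", 10, "S"), SiteKey("P1", 50, "S"),
             SiteKey("P2", 10, "S"), SiteKey("P3", 10, "S"),
             SiteKey("P4", 10, "S")]
    hits = _hits_frame([
        ("P1", 100, 105, "B55H", 5.0, 1e-5),
        ("P2", 100, 105, "B56", 5.0, 1e-5),
        ("P3", 100, 105, "B55b", 5.0, 1e-5),
        ("P3", 200, 205, "B56", 5.0, 1e-5),
    ])
    counts = pc.count_slim_site_assignments(sites, hits, DEFAULT_FAMILY_OF)
    assert counts == {"B55_only": 2, "B56_only": 1, "both": 1, "none": 1}
    assert sum(counts.values()) == len(sites)


def test_slim_counts_match_brute_force_on_random_fixture():
    rng = np.random.default_rng(20)
    accs = [f"P{i}" for i in range(30)]
    sites = [SiteKey(accs[int(rng.integers(30))], int(p), "S")
             for p in rng.integers(1, 400, size=120)]
    hit_rows = []
    fams = ["B56", "B55b", "B55H", "B55H2"]
    for _ in range(60):
        acc = accs[int(rng.integers(30))]
        start = int(rng.integers(1, 350))
        hit_rows.append((acc, start, start + 5, fams[int(rng.integers(4))],
                         5.0, 1e-5))
    hits = _hits_frame(hit_rows)
    counts = pc.count_slim_site_assignments(sites, hits, DEFAULT_FAMILY_OF)
    # brute force tabulation
    by_acc = {}
    for row in hit_rows:
        by_acc.setdefault(row[0], set()).add(DEFAULT_FAMILY_OF[row[3]])
    brute = {"B55_only": 0, "B56_only": 0, "both": 0, "none": 0}
    for s in sites:
        f = by_acc.get(s.accession, set())
        key = ("both" if f == {"B55", "B56"} else
               "B55_only" if f == {"B55"} else
               "B56_only" if f == {"B56"} else "none")
        brute[key] += 1
    assert counts == brute
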