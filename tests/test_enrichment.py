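import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from effimm.enrichment import (
    aggregate_structural,
    benjamini_hochberg,
    group_enrichment,
    kruskal_wallis,
    longitudinal_trend,
    normalize_hits,
    read_domtblout,
    read_hit_tsv,
    slope_by_group,
)
from effimm.synthdata import HitTable, simulate_hit_tables, simulate_longitudinal_cohort


def small_table(counts, reads, abundance, groups):
    samples = [f"s{i}" for i in range(len(reads))]
    return HitTable(
        counts=pd.DataFrame(counts, index=samples, columns=[f"f{j}" for j in range(np.shape(counts)[1])]),
        read_totals=pd.Series(reads, index=samples),
        bact_abundance=pd.Series(abundance, index=samples),
        sample_meta=pd.DataFrame({"group": groups, "subject": samples, "week": 0}, index=samples),
    )


def test_normalization_definition_arithmetic():
    t = small_table([[10], [0]], [1e7, 1e7], [0.5, 0.5], ["UC", "CD"])
    norm = normalize_hits(t)
    assert norm.iloc[0, 0] == pytest.approx(2.0)
    assert norm.iloc[1, 0] == 0.0


def test_normalization_scaling_law_and_dropped_samples():
    t = small_table([[10], [10], [10]], [1e7, 2e7, 1e7], [0.5, 0.5, 0.0], ["UC", "CD", "CD"])
    norm = normalize_hits(t)
    assert norm.iloc[1, 0] == pytest.approx(norm.iloc[0, 0] / 2)  # doubling reads halves values
    assert len(norm) == 2  # zero-abundance sample dropped


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        small_table([[-1]], [1e7], [0.5], ["UC"])


def test_bh_analytic_step_up_case():
    q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_and_never_below_p(rng):
    p = rng.uniform(size=40)
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_kruskal_degenerate_constant_input():
    h, p = kruskal_wallis([np.ones(5), np.ones(5)])
    assert h == 0.0 and p == 1.0


def exact_permutation_p(vals, n_a):
    """Exact permutation p-value of the Kruskal-Wallis H for two groups:
    every split of the observations enumerated."""
    h_obs, _ = kruskal_wallis([vals[:n_a], vals[n_a:]])
    idx = range(len(vals))
    count = total = 0
    for comb in itertools.combinations(idx, n_a):
        a = vals[list(comb)]
        b = vals[[i for i in idx if i not in comb]]
        h, _ = kruskal_wallis([a, b])
        total += 1
        count += h >= h_obs - 1e-12
    return count / total


def test_kruskal_matches_exact_permutation_null():
    """The chi-square p tracks the exact permutation null on 5-per-group
    fixtures (252 splits enumerated).  At these sample sizes the chi-square
    approximation is known to carry absolute error on the 0.1 scale, which
    bounds the agreement demanded here."""
    diffs = []
    for seed, shift in [(1, 1.0), (2, 0.8), (3, 1.5), (5, 1.2), (7, 0.5), (11, 1.2)]:
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=10)
        vals[:5] += shift
        _, p_chi2 = kruskal_wallis([vals[:5], vals[5:]])
        diffs.append(abs(p_chi2 - exact_permutation_p(vals, 5)))
    assert max(diffs) <= 0.1


def test_enrichment_identical_groups_flat():
    t = small_table([[5], [5], [5], [5]], [1e7] * 4, [0.5] * 4, ["UC", "UC", "CD", "CD"])
    res = group_enrichment(normalize_hits(t), t.sample_meta["group"])
    assert res["H"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0


def test_enrichment_rankbased_scale_invariance():
    tab, _ = simulate_hit_tables(n_samples_per_group=10, n_families=12, seed=4)
    norm = normalize_hits(tab)
    res1 = group_enrichment(norm, tab.sample_meta["group"])
    res2 = group_enrichment(norm * 17.3, tab.sample_meta["group"])
    np.testing.assert_allclose(res1["p_value"], res2["p_value"])


def test_planted_effect_detected_with_calibrated_null():
    """3-fold planted UC enrichment: detected at q < 0.05 in >= 90% of sims,
    with false positives per sim at the BH-controlled level."""
    n_sims = 40  # subset here; the full 200-sim run lives in the acceptance suite
    hits = 0
    fps = []
    for s in range(n_sims):
        tab, _ = simulate_hit_tables(
            n_samples_per_group=30, n_families=150,
            planted={"Ntox15": {"UC": 3.0}}, lognormal_sigma=0.5, seed=1000 + s,
        )
        res = group_enrichment(normalize_hits(tab), tab.sample_meta["group"])
        if res.loc["Ntox15", "q_value"] < 0.05 and res.loc["Ntox15", "direction"] == "UC":
            hits += 1
        fps.append(int((res.drop(index="Ntox15")["q_value"] < 0.05).sum()))
    assert hits / n_sims >= 0.9
    assert np.median(fps) <= 150 * 0.05


def test_slope_exact_line():
    x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
    g = pd.Series(["UC"] * 10, index=x.index)
    fit = slope_by_group(x, x, g)[0]
    assert fit.slope == pytest.approx(1.0)
    assert fit.ci_low == pytest.approx(1.0, abs=1e-9)
    assert fit.ci_high == pytest.approx(1.0, abs=1e-9)


def test_slope_zero_response():
    x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
    y = pd.Series(np.zeros(10), index=x.index)
    g = pd.Series(["CD"] * 10, index=x.index)
    fit = slope_by_group(y, x, g)[0]
    assert fit.slope == pytest.approx(0.0)


def test_slope_recovery_simulation():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 10, 200)
    y = 0.5 * x + rng.normal(0, 0.1, 200)
    idx = [f"s{i}" for i in range(200)]
    fit = slope_by_group(pd.Series(y, index=idx), pd.Series(x, index=idx),
                         pd.Series(["UC"] * 200, index=idx))[0]
    assert fit.slope == pytest.approx(0.5, abs=0.05)
    assert fit.ci_low <= 0.5 <= fit.ci_high


def test_slope_undefined_for_constant_predictor():
    x = pd.Series(np.ones(10), index=[f"s{i}" for i in range(10)])
    g = pd.Series(["UC"] * 10, index=x.index)
    fit = slope_by_group(x, x, g)[0]
    assert fit.undefined and fit.slope is None


def test_trend_constant_and_linear_series():
    df = pd.DataFrame({
        "value": [5.0] * 5 + list(range(5)),
        "subject": ["a"] * 5 + ["b"] * 5,
        "week": list(range(5)) * 2,
        "group": ["UC"] * 10,
    })
    tr = longitudinal_trend(df["value"], df["subject"], df["week"], df["group"])
    slopes = tr.subject_slopes.set_index("subject")["slope"]
    assert slopes["a"] == pytest.approx(0.0, abs=1e-12)
    assert slopes["b"] == pytest.approx(1.0)


def test_trend_excludes_short_series():
    df = pd.DataFrame({
        "value": [1.0, 2.0, 1, 2, 3],
        "subject": ["a", "a", "b", "b", "b"],
        "week": [0, 1, 0, 1, 2],
        "group": ["UC"] * 5,
    })
    tr = longitudinal_trend(df["value"], df["subject"], df["week"], df["group"])
    assert set(tr.subject_slopes["subject"]) == {"b"}


def test_trend_detects_planted_uc_drift():
    detected = 0
    n_sims = 20  # the 100-sim version runs in the acceptance suite
    for s in range(n_sims):
        coh = simulate_longitudinal_cohort(
            n_subjects_per_group=20, n_weeks=10,
            drift_per_group={"UC": 0.2}, noise_sd=0.5, seed=500 + s,
        )
        tr = longitudinal_trend(coh["value"], coh["subject"], coh["week"], coh["group"])
        p_uc = tr.group_tests.set_index("group").loc["UC", "p_value"]
        if p_uc < 0.05:
            detected += 1
    assert detected / n_sims >= 0.8


def test_aggregate_structural_excludes_blacklist():
    cols = ["TssB", "TssC", "TssH", "Ntox15"]
    norm = pd.DataFrame([[1.0, 2.0, 100.0, 7.0]], index=["s0"], columns=cols)
    agg = aggregate_structural(norm, structural_families=cols[:3])
    assert agg.iloc[0] == pytest.approx(3.0)  # TssH never counted


DOMTBLOUT = """\
#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
seq1                 -            200 TssB                 -            100     1e-30  100.0   0.0   1   2   1e-20     2e-20    50.0   0.0     1   100     1   100     1   100 0.98 -
seq1                 -            200 TssB                 -            100     1e-30  100.0   0.0   2   2   1e-10     2e-10    30.0   0.0     1   100   101   200   101   200 0.98 -
seq2                 -            150 TssB                 -            100     1e-08   40.0   0.0   1   1   1e-08     1e-08    40.0   0.0     1   100     1   100     1   100 0.95 -
seq3                 -            150 TssB                 -            100     1e-03   10.0   0.0   1   1   1e-03     1e-03    10.0   0.0     1   100     1   100     1   100 0.90 -
"""


def test_domtblout_one_hit_per_target_with_threshold(tmp_path):
    p = tmp_path / "hits.domtblout"
    p.write_text(DOMTBLOUT)
    # seq1 has two domains but counts once; seq3 fails the 1e-5 threshold
    assert read_domtblout(p, family="TssB") == 2
    assert read_domtblout(p, family="TssB", evalue_threshold=1e-2) == 3
    assert read_domtblout(p, family="TssC") == 0


def test_hit_tsv_round_trip(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("sample\tfamily\tcount\ns1\tTssB\t3\ns1\tNtox15\t1\ns2\tTssB\t0\n")
    mat = read_hit_tsv(p)
    assert mat.loc["s1", "TssB"] == 3
    assert mat.loc["s2", "Ntox15"] == 0
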