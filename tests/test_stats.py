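"""Statistical layer: summary ANOVA, Tukey-Kramer, Spearman, RMSD/CV."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from stenoflow import (
    SummaryStats,
    anova_from_replicates,
    anova_from_summary,
    rmsd_cv,
    spearman_correlation,
    tukey_kramer_from_summary,
)
from stenoflow.stats import summarize_replicates

GRADES = ["0", "40", "60", "80"]


def make_summary(means, sds, ns=(3, 3, 3, 3)):
    return SummaryStats(GRADES[: len(means)], np.asarray(means), np.asarray(sds), np.asarray(ns))


def triples(mean, sd):
    """Three values with exactly the requested mean and sample SD."""
    return np.array([mean - sd, mean, mean + sd])


# --- one-way ANOVA from summary statistics ---------------------------------


def test_anova_matches_published_summary_row():
    """Four groups of n=3 with strong distal separation give p ~ 4e-4."""
    res = anova_from_summary(make_summary([29.75, 7.84, 8.49, -9.18], [4.34, 11.3, 1.37, 1.63]))
    assert res.df_between == 3 and res.df_within == 8
    assert res.p_value == pytest.approx(0.0004, abs=5e-5)


def test_anova_equal_means_gives_f_zero_p_one():
    res = anova_from_summary(make_summary([5.0, 5.0, 5.0], [1.0, 2.0, 3.0], (3, 3, 3)))
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0


def test_anova_degenerate_variance_unequal_means_warns_p_zero():
    with pytest.warns(RuntimeWarning, match="zero within-group variance"):
        res = anova_from_summary(make_summary([1.0, 2.0], [0.0, 0.0], (3, 3)))
    assert res.p_value == 0.0 and np.isinf(res.f_statistic)


def test_anova_fully_degenerate_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        anova_from_summary(make_summary([2.0, 2.0], [0.0, 0.0], (3, 3)))


def test_summary_stats_validation():
    with pytest.raises(ValueError, match="equal length"):
        SummaryStats(["a", "b"], [1.0], [1.0], [3])
    with pytest.raises(ValueError, match="non-negative"):
        make_summary([1.0, 2.0], [-1.0, 1.0], (3, 3))
    with pytest.raises(ValueError, match="n >= 2"):
        make_summary([1.0, 2.0], [1.0, 1.0], (1, 3))


@given(
    means=st.lists(st.floats(-50, 50), min_size=2, max_size=5),
    sds=st.data(),
)
def test_summary_anova_equals_raw_anova_on_constructed_triples(means, sds):
    """Summary-statistics ANOVA is an algebraic identity with raw ANOVA."""
    sd_values = [
        sds.draw(st.floats(0.1, 20.0), label=f"sd{i}") for i in range(len(means))
    ]
    groups = [triples(m, s) for m, s in zip(means, sd_values)]
    mine = anova_from_summary(
        SummaryStats([str(i) for i in range(len(means))],
                     [g.mean() for g in groups],
                     [g.std(ddof=1) for g in groups],
                     [3] * len(means))
    )
    f_ref, p_ref = sps.f_oneway(*groups)
    assert mine.f_statistic == pytest.approx(f_ref, rel=1e-9, abs=1e-12)
    assert mine.p_value == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def test_anova_from_replicates_agrees_with_summary_route():
    rng = np.random.default_rng(7)
    groups = {g: rng.normal(float(g), 5.0, size=4) for g in GRADES}
    from_reps = anova_from_replicates(groups)
    from_summary = anova_from_summary(summarize_replicates(groups))
    assert from_reps == from_summary


def test_anova_from_replicates_identical_groups():
    res = anova_from_replicates({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert res.f_statistic == 0.0 and res.p_value == 1.0


# --- Tukey-Kramer ----------------------------------------------------------


def test_tukey_reproduces_published_pairwise_p():
    """Low- vs high-grade comparison from a published distal summary row."""
    stats = make_summary([46.78, 25.94, 9.89, -5.64], [8.27, 15.81, 6.81, 6.1])
    res = tukey_kramer_from_summary(stats, ("40", "80"))
    assert res.adjusted_p == pytest.approx(0.0202, abs=3e-4)


def test_tukey_symmetric_and_identical_means():
    stats = make_summary([10.0, 10.0, 3.0], [2.0, 2.0, 2.0], (3, 3, 3))
    ab = tukey_kramer_from_summary(stats, ("0", "40"))
    ba = tukey_kramer_from_summary(stats, ("40", "0"))
    assert ab.adjusted_p == ba.adjusted_p
    assert ab.q_statistic == ba.q_statistic
    assert ab.mean_difference == -ba.mean_difference
    assert ab.q_statistic == 0.0 and ab.adjusted_p == 1.0
    with pytest.raises(ValueError, match="distinct"):
        tukey_kramer_from_summary(stats, ("0", "0"))


def test_tukey_agrees_with_statsmodels_on_raw_triples():
    statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
    means, sds = [29.75, 7.84, 8.49, -9.18], [4.34, 11.3, 1.37, 1.63]
    data = np.concatenate([triples(m, s) for m, s in zip(means, sds)])
    labels = np.repeat(GRADES, 3)
    ref = statsmodels.pairwise_tukeyhsd(data, labels)
    summary = make_summary(means, sds)
    for row, p_ref in zip(ref._results_table.data[1:], ref.pvalues):
        a, b = row[0], row[1]
        mine = tukey_kramer_from_summary(summary, (str(a), str(b)))
        assert mine.adjusted_p == pytest.approx(p_ref, abs=1e-3)


@given(
    means=st.lists(st.floats(-30, 30), min_size=3, max_size=4),
    sd=st.floats(0.5, 10.0),
)
def test_tukey_p_at_least_unadjusted_t_p(means, sd):
    """Multiplicity ordering: adjusted p >= plain pairwise t-test p."""
    k = len(means)
    stats = make_summary(means, [sd] * k, (3,) * k)
    mse = sd**2  # equal SDs, equal n
    dfw = 2 * k
    for i in range(k - 1):
        tk = tukey_kramer_from_summary(stats, (GRADES[i], GRADES[i + 1]))
        t = abs(means[i] - means[i + 1]) / np.sqrt(mse * (2.0 / 3.0))
        p_t = 2.0 * sps.t.sf(t, dfw)
        assert tk.adjusted_p >= p_t - 1e-12


# --- Spearman --------------------------------------------------------------


def test_spearman_perfect_monotone_decreasing():
    rho, _ = spearman_correlation([10, 6, 4, 2], [-1.0, -2.5, -3.0, -7.0][::-1])
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_ties_match_bruteforce_rank_computation():
    x = [10.0, 10.0, 6.0, 4.0, 2.0, 2.0]
    y = [3.0, 5.0, 1.0, 1.0, -2.0, -4.0]

    def average_ranks(v):
        v = np.asarray(v)
        ranks = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            ranks[i] = less + (equal + 1) / 2.0  # average rank over the tie block
        return ranks

    expected = np.corrcoef(average_ranks(x), average_ranks(y))[0, 1]
    rho, _ = spearman_correlation(x, y)
    assert rho == pytest.approx(expected, abs=1e-12)


# --- RMSD / CV -------------------------------------------------------------


def test_rmsd_identical_replicates_is_zero():
    res = rmsd_cv({"a": [5.0, 5.0, 5.0], "b": [7.0, 7.0, 7.0]}, 5.0)
    assert res.rmsd == 0.0 and res.cv_pct == 0.0


def test_rmsd_hand_computed_two_conditions():
    res = rmsd_cv({"a": [0.0, 2.0], "b": [10.0, 12.0]}, 3.0)
    assert res.rmsd == pytest.approx(np.sqrt(2.0))
    assert res.cv_pct == pytest.approx(100.0 * np.sqrt(2.0) / 6.0)


def test_cv_invariant_under_rescaling(rng):
    conditions = {c: rng.uniform(10, 100, size=3) for c in "abcd"}
    base = rmsd_cv(conditions, 1.0)
    scaled = rmsd_cv({c: 7.3 * v for c, v in conditions.items()}, 1.0)
    assert scaled.cv_pct == pytest.approx(base.cv_pct, rel=1e-12)
    assert scaled.rmsd == pytest.approx(7.3 * base.rmsd, rel=1e-12)


def test_rmsd_single_replicate_rejected():
    with pytest.raises(ValueError, match="single replicate"):
        rmsd_cv({"a": [1.0]}, 1.0)
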