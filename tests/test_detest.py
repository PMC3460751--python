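"""Negative-binomial exact test: oracles, calibration and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polytag import detest, simulate


def _enumeration_oracle(sa, na, sb, nb, phi):
    """Direct enumeration of all t+1 splits of the conditional distribution."""
    t = sa + sb
    mu = t / (na + nb)
    a = np.arange(t + 1)
    if phi == 0:
        pa = stats.poisson.pmf(a, na * mu)
        pb = stats.poisson.pmf(t - a, nb * mu)
    else:
        ra, rb = na / phi, nb / phi
        pa = stats.nbinom.pmf(a, ra, ra / (ra + na * mu))
        pb = stats.nbinom.pmf(t - a, rb, rb / (rb + nb * mu))
    pr = pa * pb
    pr /= pr.sum()
    return min(1.0, pr[pr <= pr[sa] * (1 + 1e-12)].sum())


def _nb_counts(rng, mu, phi, n_genes, n_lanes):
    cols = {}
    for j in range(n_lanes):
        lam = rng.gamma(1 / phi, phi * mu) if phi > 0 else mu
        cols[f"l{j}"] = rng.poisson(lam)
    return pd.DataFrame(cols)


@pytest.mark.parametrize(
    "sa,na,sb,nb,phi",
    [(8, 3, 2, 3, 0.1), (12, 3, 4, 3, 0.15), (0, 3, 9, 3, 0.3),
     (15, 2, 15, 2, 0.05), (1, 3, 0, 3, 0.2), (20, 3, 10, 2, 0.0)],
)
def test_exact_test_equals_enumeration(sa, na, sb, nb, phi):
    assert detest.exact_test(sa, na, sb, nb, phi) == pytest.approx(
        _enumeration_oracle(sa, na, sb, nb, phi), rel=1e-9
    )


def test_exact_test_poisson_limit_is_conditional_binomial():
    """phi -> 0: the conditional distribution is Binomial(t, nA/(nA+nB))."""
    for sa, sb in [(8, 2), (5, 5), (30, 12)]:
        p_nb = detest.exact_test(sa, 3, sb, 3, 0.0)
        p_bin = stats.binomtest(sa, sa + sb, 0.5).pvalue
        assert p_nb == pytest.approx(p_bin, rel=1e-9)
        p_small_phi = detest.exact_test(sa, 3, sb, 3, 1e-8)
        assert p_small_phi == pytest.approx(p_bin, rel=1e-4)


def test_exact_test_symmetric_split_is_one():
    assert detest.exact_test(7, 3, 7, 3, 0.2) == pytest.approx(1.0)
    assert detest.exact_test(0, 3, 0, 3, 0.2) == 1.0  # t=0 by convention


def test_exact_test_rejects_negative_phi():
    with pytest.raises(ValueError):
        detest.exact_test(1, 3, 1, 3, -0.1)


def test_bh_adjust_step_up_hand_example():
    # step-up: p_(i) * n / i then monotone from the largest rank down
    assert detest.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert detest.bh_adjust([0.5]) == pytest.approx([0.5])
    assert detest.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def test_bh_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.uniform(size=200)
    ours = detest.bh_adjust(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)


def test_dispersion_recovery_nb():
    """phi-hat recovers the simulated common dispersion."""
    rng = np.random.default_rng(100)
    mu = rng.gamma(2, 50, 1000)
    counts = _nb_counts(rng, mu, 0.2, 1000, 6)
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    est = detest.estimate_common_dispersion(detest.CountMatrix(counts, groups))
    assert 0.15 <= est.phi <= 0.25


def test_dispersion_recovery_poisson():
    rng = np.random.default_rng(101)
    mu = rng.gamma(2, 50, 1000)
    counts = _nb_counts(rng, mu, 0.0, 1000, 6)
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    est = detest.estimate_common_dispersion(detest.CountMatrix(counts, groups))
    assert est.phi < 0.02


def test_dispersion_needs_replicates():
    counts = pd.DataFrame({"a": [3, 5], "b": [4, 9]})
    groups = pd.Series({"a": "E", "b": "F"})
    with pytest.raises(ValueError, match="replicate"):
        detest.estimate_common_dispersion(detest.CountMatrix(counts, groups))


def test_all_zero_gene_ignored_without_failure():
    rng = np.random.default_rng(5)
    counts = _nb_counts(rng, np.full(50, 40.0), 0.1, 50, 6)
    counts.iloc[7] = 0
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    res, est = detest.de_analysis(counts, groups)
    assert res.iloc[7]["call"] == "not_tested"
    assert res.drop(res.index[7])["p_value"].notna().all()


def test_null_calibration_and_bh_control():
    """No DE: ~5% raw p < 0.05, essentially no BH calls at alpha=0.05."""
    cfg = simulate.SimulationConfig(
        n_loci=1000, de_fraction=0.0, dispersion=0.1, library_size=100_000, seed=21
    )
    _, _, _, truth = simulate.simulate_reference(cfg)
    counts, groups = simulate.simulate_count_matrix(truth, cfg)
    res, _ = detest.de_analysis(counts, groups)
    p = res["p_value"].dropna()
    assert 0.02 <= (p < 0.05).mean() <= 0.08
    assert (res["call"].isin(["up_E", "up_F"])).sum() <= 2


def test_power_and_fdr_on_true_de():
    """10% DE at log2FC=2: >80% recovery with empirical FDR < 10%."""
    cfg = simulate.SimulationConfig(
        n_loci=1000, de_fraction=0.10, log2_fc=2.0, dispersion=0.1,
        library_size=100_000, seed=22,
    )
    _, _, _, truth = simulate.simulate_reference(cfg)
    counts, groups = simulate.simulate_count_matrix(truth, cfg)
    res, _ = detest.de_analysis(counts, groups)
    merged = truth.loci.set_index("locus_id").join(res)
    called = merged["call"].isin(["up_E", "up_F"])
    true_de = merged["de"] != "none"
    recovery = (called & true_de).sum() / true_de.sum()
    fdr = (called & ~true_de).sum() / max(called.sum(), 1)
    assert recovery > 0.8
    assert fdr < 0.10
    hits = merged[called & true_de]
    assert (hits["call"] == hits["de"]).all()  # directions agree with truth


def test_group_swap_negates_m_keeps_p():
    rng = np.random.default_rng(9)
    counts = _nb_counts(rng, rng.gamma(2, 30, 80), 0.1, 80, 6)
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    res1, _ = detest.de_analysis(counts, groups, labels=["E", "F"])
    res2, _ = detest.de_analysis(counts, groups, labels=["F", "E"])
    keep = res1["call"] != "not_tested"
    assert np.allclose(res1.loc[keep, "M"], -res2.loc[keep, "M"])
    assert np.allclose(res1.loc[keep, "p_value"], res2.loc[keep, "p_value"])


def test_exact_test_exchangeable_within_group():
    rng = np.random.default_rng(10)
    counts = _nb_counts(rng, rng.gamma(2, 30, 60), 0.1, 60, 6)
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    res1, _ = detest.de_analysis(counts, groups)
    shuffled = counts[["l2", "l0", "l1", "l5", "l3", "l4"]]
    res2, _ = detest.de_analysis(shuffled, groups)
    keep = res1["call"] != "not_tested"
    assert np.allclose(res1.loc[keep, "p_value"], res2.loc[keep, "p_value"])


def test_zero_group_gets_large_finite_m():
    counts = pd.DataFrame(
        {"l0": [500, 10], "l1": [480, 12], "l2": [510, 9],
         "l3": [0, 11], "l4": [0, 10], "l5": [0, 12]}
    )
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    res, _ = detest.de_analysis(counts, groups, labels=["E", "F"])
    m = res.iloc[0]["M"]
    assert np.isfinite(m) and m > 5


def test_call_thresholds():
    """Calls follow |M| > 0.58 and adj_p < 0.05 jointly."""
    pseudo = pd.DataFrame(
        {"l0": [10.0], "l1": [10.0], "l2": [12.0], "l3": [3.0], "l4": [2.0], "l5": [4.0]}
    )
    groups = pd.Series({f"l{j}": "E" if j < 3 else "F" for j in range(6)})
    res = detest.compute_m_and_call(
        pseudo, groups, ["E", "F"], 1000.0, pd.Series([0.01], index=pseudo.index)
    )
    assert res.iloc[0]["M"] > 0.58 and res.iloc[0]["call"] == "up_E"
    res2 = detest.compute_m_and_call(
        pseudo, groups, ["E", "F"], 1000.0, pd.Series([0.06 * 1], index=pseudo.index)
    )
    assert res2.iloc[0]["adj_p"] >= 0.05 and res2.iloc[0]["call"] == "not_DE"
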