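"""R statistic, p-value calibration, BH-FDR and DE calling.

The R statistic's oracle is an independent numeric maximization of the
Poisson likelihood (free rate per library vs a shared rate), so the
log-likelihood-ratio identity is checked without reusing the closed form.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from curdseq.de import DESummary, bh_fdr, call_de, fold_change, p_from_r, r_statistic
from curdseq.quantify import CountTable, RPKMTable, compute_rpkm
from curdseq.synthetic import DEDesign, simulate_counts


# ------------------------------------------------------------- R statistic


def _poisson_lrt_numeric(x, N):
    """2·log-likelihood-ratio by numeric maximization (independent oracle)."""
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)

    def nll_one(lam, xi):
        # -log Poisson(xi; lam) up to the constant log(xi!)
        if lam <= 0:
            return np.inf if xi > 0 else 0.0
        return lam - xi * np.log(lam)

    ll_alt = 0.0
    for xi in x:
        res = optimize.minimize_scalar(
            nll_one, args=(xi,), bounds=(1e-12, max(xi, 1.0) * 10 + 10),
            method="bounded", options={"xatol": 1e-12},
        )
        ll_alt -= res.fun

    def nll_null(f):
        return sum(nll_one(f * Ni, xi) for xi, Ni in zip(x, N))

    guess = max(x.sum() / N.sum(), 1e-9)
    res = optimize.minimize_scalar(
        nll_null, bounds=(guess / 100, guess * 100 + 1e-6),
        method="bounded", options={"xatol": 1e-14},
    )
    ll_null = -res.fun
    return 2.0 * (ll_alt - ll_null)


def test_r_statistic_equal_proportions_zero():
    assert r_statistic([7, 7], [1000, 1000]) == 0.0
    assert r_statistic([0, 0], [1000, 2000]) == 0.0


def test_r_statistic_rejects_bad_input():
    with pytest.raises(ValueError):
        r_statistic([-1, 2], [10, 10])
    with pytest.raises(ValueError):
        r_statistic([1, 2], [0, 10])
    with pytest.raises(ValueError):
        r_statistic([3], [10])


def test_r_statistic_symmetry_under_permutation():
    x, N = [5, 50, 12], [1000.0, 2000.0, 1500.0]
    r = r_statistic(x, N)
    perm = [2, 0, 1]
    assert r_statistic([x[i] for i in perm], [N[i] for i in perm]) == pytest.approx(r)


def test_two_r_matches_numeric_poisson_lrt():
    # >= 100 random small count vectors across 2-4 libraries
    rng = np.random.default_rng(51)
    checked = 0
    while checked < 120:
        m = int(rng.integers(2, 5))
        N = rng.integers(10**3, 10**6, size=m).astype(float)
        x = rng.poisson(rng.uniform(0, 60), size=m).astype(float)
        if x.sum() == 0:
            continue
        r = r_statistic(x, N)
        lrt = _poisson_lrt_numeric(x, N)
        assert abs(2 * r - lrt) < 1e-8, (x, N)
        checked += 1


# ------------------------------------------------------------- p-values


def test_p_from_r_chi2_reference_points():
    assert p_from_r(0.0, 2) == 1.0
    # 2R = 3.841 at 1 df is the 5% critical point
    assert p_from_r(3.841 / 2, 2) == pytest.approx(0.05, abs=1e-4)


def test_bootstrap_agrees_with_chi2_at_large_counts():
    x, N = np.array([1000.0, 1100.0]), np.array([1e6, 1e6])
    r = r_statistic(x, N)
    p_chi2 = p_from_r(r, 2)
    n_boot = 10_000
    p_boot = p_from_r(r, 2, method="bootstrap", x=x, N=N, n_boot=n_boot, seed=52)
    se = np.sqrt(p_chi2 * (1 - p_chi2) / n_boot)
    assert abs(p_boot - p_chi2) < 3 * se + 0.005


def test_bootstrap_parameter_validation():
    with pytest.raises(ValueError):
        p_from_r(1.0, 2, method="bootstrap", x=[1, 2], N=[10, 10], n_boot=0)


# ------------------------------------------------------------- BH FDR


def _bh_brute(p):
    """Exhaustive min-over-tails definition of the BH adjusted value."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank - 1, m)]
        q[idx] = min(1.0, min(tail))
    return q


def test_bh_trivial_cases():
    assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)
    assert bh_fdr([0.07]) == pytest.approx([0.07])


def test_bh_matches_brute_force_definition():
    cases = [np.array([0.01, 0.02, 0.03, 0.04])]
    rng = np.random.default_rng(53)
    cases += [rng.uniform(size=rng.integers(2, 30)) for _ in range(25)]
    for p in cases:
        assert np.allclose(bh_fdr(p), _bh_brute(p))


def test_bh_order_invariance_and_bonferroni_bound():
    rng = np.random.default_rng(54)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))
    assert (bh_fdr(p) <= np.minimum(p * 50, 1.0) + 1e-12).all()


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


# ------------------------------------------------------------- fold change


@pytest.mark.parametrize(
    "test,ref,expected,decimals",
    [
        (320.0, 50.6, 6.32411, 5),  # published expression-table row
        (23.1, 0.0, 23.1, 1),  # zero-reference convention
        (5.5, 5.5, 1.0, 7),
        (0.0, 0.0, 1.0, 7),
        (0.5, 59.2, 0.01, 2),
    ],
)
def test_fold_change_conventions(test, ref, expected, decimals):
    assert round(fold_change(test, ref), decimals) == pytest.approx(
        expected, abs=10**-decimals / 2
    )


def test_fold_change_rejects_negative():
    with pytest.raises(ValueError):
        fold_change(-1.0, 2.0)


# ------------------------------------------------------------- call_de


def _tables_from_counts(counts, lengths=None):
    lengths = lengths or {g: 1000 for g in counts.index}
    table = CountTable(counts, counts.sum(axis=0))
    return table, compute_rpkm(table, lengths)


def test_identical_proportions_give_zero_calls():
    idx = pd.Index([f"g{i}" for i in range(20)], name="unigene_id")
    counts = pd.DataFrame({"white": range(20), "green": range(20)}, index=idx)
    table, rpkm = _tables_from_counts(counts)
    result, summary = call_de(table, rpkm)
    assert summary.n_up == summary.n_down == 0
    assert (result["call"] == "none").all()


def test_zero_count_genes_excluded_from_batch():
    idx = pd.Index(["a", "b", "c"], name="unigene_id")
    counts = pd.DataFrame({"white": [0, 5, 800], "green": [0, 6, 100]}, index=idx)
    table, rpkm = _tables_from_counts(counts)
    result, summary = call_de(table, rpkm)
    assert np.isnan(result.loc["a", "p"])
    assert summary.n_tested == 2


def test_summary_percentages():
    assert DESummary.percentage(4436, 118000) == 3.76
    assert round(DESummary.percentage(2719, 118000), 1) == 2.3


def test_planted_de_recovered_with_fdr_control():
    # 10% fold-10 genes with reference mean >= 50: all recovered, and the
    # empirical FDR among calls stays within Monte-Carlo slack of the target
    design = DEDesign(fraction_up=0.05, fraction_down=0.05,
                      fold_values=(10.0,), depth=100_000)
    counts, genes = simulate_counts(500, design, seed=55, planted_min_mean=50)
    table, rpkm = _tables_from_counts(counts)
    result, summary = call_de(table, rpkm, fdr_max=0.01, min_fold=3.0)
    called_up = set(result.index[result["call"] == "up"])
    called_down = set(result.index[result["call"] == "down"])
    planted_up = set(genes.index[genes["de_flag"] == "up"])
    planted_down = set(genes.index[genes["de_flag"] == "down"])
    assert planted_up <= called_up
    assert planted_down <= called_down
    n_calls = len(called_up | called_down)
    n_false = len((called_up | called_down) - (planted_up | planted_down))
    assert n_false / max(n_calls, 1) <= 0.05


def test_null_type_one_error_controlled():
    design = DEDesign(fraction_up=0.0, fraction_down=0.0, depth=100_000)
    counts, _ = simulate_counts(1000, design, seed=56)
    table, rpkm = _tables_from_counts(counts)
    _, summary = call_de(table, rpkm, fdr_max=0.01, min_fold=3.0)
    frac = (summary.n_up + summary.n_down) / summary.n_tested
    mc_se = np.sqrt(0.01 * 0.99 / summary.n_tested)
    assert frac <= 0.01 + 3 * mc_se


def test_mismatched_tables_rejected():
    idx = pd.Index(["a", "b"], name="unigene_id")
    counts = pd.DataFrame({"white": [1, 2], "green": [3, 4]}, index=idx)
    table, rpkm = _tables_from_counts(counts)
    other = RPKMTable(rpkm.rpkm.iloc[:1], rpkm.lengths.iloc[:1])
    with pytest.raises(ValueError):
        call_de(table, other)
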