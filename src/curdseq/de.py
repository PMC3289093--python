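"""Differential-expression calling for digital (count-based) expression data.

The test statistic is the log-likelihood-ratio R statistic for count data
across sequencing libraries: with observed counts x_i in libraries of
total size N_i and pooled proportion f = Σx_i / ΣN_i,

    R = Σ_{x_i > 0} x_i · ln( x_i / (N_i · f) )

R is the Poisson log-likelihood ratio between a model with a free rate per
library and a shared-rate null, so 2R is asymptotically chi-square with
(number of libraries − 1) degrees of freedom; that is the default p-value
calibration, with a Poisson parametric bootstrap available for low counts.
Raw p-values are adjusted by Benjamini–Hochberg FDR, and a unigene is
called differentially expressed when q ≤ 0.01 and the RPKM fold change is
at least 3 (up) or at most 1/3 (down).

Fold-change convention (test/reference, i.e. green/white): when the
reference RPKM is 0 and the test RPKM positive, the reported fold equals
the test RPKM (a unit denominator); when both are 0 the fold is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountTable, RPKMTable


def r_statistic(x, N) -> float:
    """Log-likelihood-ratio statistic for counts x across libraries of size N."""
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)
    if x.shape != N.shape or x.size < 2:
        raise ValueError("x and N must be equal-length vectors with >= 2 libraries")
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    if (N <= 0).any():
        raise ValueError("library totals must be > 0")
    total = x.sum()
    if total == 0:
        return 0.0
    f = total / N.sum()
    nz = x > 0
    r = float(np.sum(x[nz] * np.log(x[nz] / (N[nz] * f))))
    return max(r, 0.0)


def _r_statistic_rows(x: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Vectorized R over rows of a (genes x libraries) count matrix."""
    total = x.sum(axis=1)
    f = np.where(total > 0, total / N.sum(), 1.0)
    expected = N[None, :] * f[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / expected), 0.0)
    return np.clip(terms.sum(axis=1), 0.0, None)


def p_from_r(
    R: float,
    m: int,
    method: str = "chi2",
    x=None,
    N=None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Null p-value for an observed R statistic.

    ``chi2``: upper tail of chi-square with m−1 df evaluated at 2R.
    ``bootstrap``: Poisson resampling under the pooled rate; the p-value
    uses the add-one convention (1 + #{R* ≥ R}) / (n_boot + 1).
    """
    if m < 2:
        raise ValueError("need at least 2 libraries")
    if method == "chi2":
        return float(stats.chi2.sf(2.0 * R, df=m - 1))
    if method == "bootstrap":
        if x is None or N is None:
            raise ValueError("bootstrap requires x and N")
        if n_boot <= 0:
            raise ValueError("n_boot must be > 0")
        x = np.asarray(x, dtype=float)
        N = np.asarray(N, dtype=float)
        f = x.sum() / N.sum()
        rng = np.random.default_rng(seed)
        sims = rng.poisson(f * N, size=(n_boot, m))
        r_star = _r_statistic_rows(sims.astype(float), N)
        return float((1 + np.sum(r_star >= R - 1e-12)) / (n_boot + 1))
    raise ValueError(f"unknown p-value method {method!r}")


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(test_rpkm: float, ref_rpkm: float) -> float:
    """Expression ratio, test over reference (green over white).

    When the reference is 0 the ratio is reported as the test value itself
    (the unit-denominator convention of the expression tables); when both
    are 0 the ratio is 1.
    """
    if test_rpkm < 0 or ref_rpkm < 0:
        raise ValueError("RPKM values must be >= 0")
    if ref_rpkm > 0:
        return test_rpkm / ref_rpkm
    if test_rpkm > 0:
        return test_rpkm
    return 1.0


@dataclass
class DESummary:
    n_total: int
    n_tested: int
    n_up: int
    n_down: int
    pct_up: float  # percentage of all unigenes, 2 d.p.
    pct_down: float

    @staticmethod
    def percentage(k: int, n: int) -> float:
        return round(100.0 * k / n, 2) if n else 0.0


def call_de(
    counts: CountTable,
    rpkm: RPKMTable,
    fdr_max: float = 0.01,
    min_fold: float = 3.0,
    test_lib: str | None = None,
    ref_lib: str | None = None,
    pvalue_method: str = "chi2",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, DESummary]:
    """Test every expressed unigene and call DE by FDR and fold thresholds.

    Unigenes with zero counts in every library are excluded from testing
    and from the BH batch.  Returns a per-unigene results frame (R, p, q,
    fold, call) and summary counts with percentages of the full unigene
    set.  Libraries default to (reference, test) = first and second column.
    """
    if list(counts.counts.index) != list(rpkm.rpkm.index) or list(
        counts.counts.columns
    ) != list(rpkm.rpkm.columns):
        raise ValueError("count and RPKM tables must share unigenes and libraries")
    if fdr_max < 0:
        raise ValueError("fdr_max must be >= 0")
    libs = counts.libraries
    if len(libs) < 2:
        raise ValueError("need at least two libraries")
    ref_lib = ref_lib or libs[0]
    test_lib = test_lib or libs[1]

    x = counts.counts.to_numpy(dtype=float)
    N = counts.library_sizes.reindex(counts.libraries).to_numpy(dtype=float)
    tested = x.sum(axis=1) > 0
    result = pd.DataFrame(index=counts.counts.index)
    result["R"] = np.nan
    result["p"] = np.nan
    result["q"] = np.nan

    if tested.any():
        if np.any(N <= 0):
            raise ValueError("library sizes must be > 0 when counts are present")
        r_vals = _r_statistic_rows(x[tested], N)
        if pvalue_method == "chi2":
            p_vals = stats.chi2.sf(2.0 * r_vals, df=len(libs) - 1)
        else:
            rng = np.random.default_rng(seed)
            p_vals = np.array(
                [
                    p_from_r(
                        r, len(libs), method=pvalue_method, x=xi, N=N,
                        n_boot=n_boot, seed=int(rng.integers(2**31)),
                    )
                    for r, xi in zip(r_vals, x[tested])
                ]
            )
        result.loc[tested, "R"] = r_vals
        result.loc[tested, "p"] = p_vals
        result.loc[tested, "q"] = bh_fdr(p_vals)

    result["fold"] = [
        fold_change(t, r)
        for t, r in zip(rpkm.rpkm[test_lib], rpkm.rpkm[ref_lib])
    ]
    sig = tested & (result["q"].to_numpy() <= fdr_max)
    fold = result["fold"].to_numpy()
    call = np.where(
        sig & (fold >= min_fold), "up", np.where(sig & (fold <= 1.0 / min_fold), "down", "none")
    )
    result["call"] = call
    n_total = len(result)
    summary = DESummary(
        n_total=n_total,
        n_tested=int(tested.sum()),
        n_up=int((call == "up").sum()),
        n_down=int((call == "down").sum()),
        pct_up=DESummary.percentage(int((call == "up").sum()), n_total),
        pct_down=DESummary.percentage(int((call == "down").sum()), n_total),
    )
    return result, summary
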