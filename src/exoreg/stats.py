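"""Statistical primitives used throughout the pipeline.

Dialects are pinned to what the downstream analyses require:

* two-sample t is the pooled-variance Student form (df = n1 + n2 - 2);
* the Wilcoxon signed-rank p-value uses the normal approximation with a
  0.5 continuity correction and tie-corrected variance (exact enumeration
  is available as an option);
* the rank-sum test is exact (full enumeration) for small tie-free
  samples and tie-corrected normal otherwise;
* the 2x2 ANOVA is balanced-only, with df = 1 per effect;
* quantile normalization is the sorted-row-mean construction with ties
  assigned the mean of their tied quantile values.

Simple wrappers delegate to scipy where scipy's convention matches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import DataError

__all__ = [
    "TestResult",
    "quantile_normalize",
    "QuantileNormalizer",
    "one_sample_t",
    "two_sample_t",
    "anova_2x2",
    "wilcoxon_signed_rank",
    "signed_rank_p",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "pearson_r",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``p_value`` is None when the test could not be computed (``flag``
    explains why); a flagged result is never silently treated as
    significant.
    """

    statistic: float
    p_value: float | None
    method: str
    df: float | None = None
    n_effective: int | None = None
    flag: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.flag is None and self.p_value is not None


# ---------------------------------------------------------------------------
# quantile normalization


class QuantileNormalizer:
    """Cross-batch quantile normalization with tie averaging.

    The reference distribution is the across-batch mean quantile function
    (for equal batch sizes this is exactly the mean of the batch-sorted
    vectors). ``transform_through`` maps values that were not part of the
    reference set (e.g. control wells) through a batch's fitted mapping by
    interpolation.
    """

    def __init__(self) -> None:
        self.batch_sorted_: dict[object, np.ndarray] = {}
        self.batch_reference_: dict[object, np.ndarray] = {}

    def fit(self, batches: dict) -> "QuantileNormalizer":
        if not batches:
            raise DataError("quantile normalization requires at least one batch")
        arrays = {}
        for key, vals in batches.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise DataError(f"empty batch {key!r}")
            arrays[key] = arr
        grids = {
            k: (np.linspace(0.0, 1.0, a.size) if a.size > 1 else np.array([0.5]))
            for k, a in arrays.items()
        }
        for k, a in arrays.items():
            ref = np.mean(
                [np.quantile(other, grids[k]) for other in arrays.values()], axis=0
            )
            self.batch_sorted_[k] = np.sort(a)
            self.batch_reference_[k] = ref
        return self

    def normalize(self, key: object, values) -> np.ndarray:
        """Normalize the batch's own reference values (tie-averaged)."""
        arr = np.asarray(values, dtype=float)
        ref = self.batch_reference_[key]
        if arr.size != ref.size:
            raise DataError("normalize() expects the values the batch was fit on")
        order = np.argsort(arr, kind="stable")
        out = np.empty_like(arr)
        sorted_vals = arr[order]
        i = 0
        while i < arr.size:
            j = i
            while j + 1 < arr.size and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            out[order[i : j + 1]] = ref[i : j + 1].mean()
            i = j + 1
        return out

    def transform_through(self, key: object, values) -> np.ndarray:
        """Map arbitrary values through the batch's fitted quantile map."""
        arr = np.asarray(values, dtype=float)
        return np.interp(arr, self.batch_sorted_[key], self.batch_reference_[key])


def quantile_normalize(batches: dict) -> dict:
    """Quantile-normalize a ``{batch_id: values}`` mapping.

    For equal-sized batches the sorted values are identical across batches
    afterwards; within-batch rank order is preserved. Unequal sizes are
    handled by linear quantile interpolation.
    """
    qn = QuantileNormalizer().fit(batches)
    return {k: qn.normalize(k, v) for k, v in batches.items()}


# ---------------------------------------------------------------------------
# t tests


def one_sample_t(x, mu0: float) -> TestResult:
    """Two-sided one-sample Student t test of mean(x) == mu0."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise DataError("one_sample_t requires n >= 2")
    if np.ptp(arr) == 0.0:
        return TestResult(
            statistic=np.nan, p_value=None, method="one_sample_t",
            df=arr.size - 1, n_effective=arr.size, flag="zero variance",
        )
    t, p = sps.ttest_1samp(arr, mu0)
    return TestResult(
        statistic=float(t), p_value=float(p), method="one_sample_t",
        df=arr.size - 1, n_effective=arr.size,
    )


def two_sample_t(x, y) -> TestResult:
    """Two-sided pooled-variance (Student) two-sample t test, df = n1+n2-2."""
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size < 2 or ay.size < 2:
        raise DataError("two_sample_t requires n >= 2 in both groups")
    df = ax.size + ay.size - 2
    if np.ptp(ax) == 0.0 and np.ptp(ay) == 0.0:
        if ax[0] == ay[0]:
            return TestResult(0.0, 1.0, "two_sample_t", df=df,
                              n_effective=ax.size + ay.size)
        return TestResult(np.nan, None, "two_sample_t", df=df,
                          n_effective=ax.size + ay.size, flag="zero variance")
    t, p = sps.ttest_ind(ax, ay, equal_var=True)
    return TestResult(float(t), float(p), "two_sample_t", df=df,
                      n_effective=ax.size + ay.size)


# ---------------------------------------------------------------------------
# 2x2 ANOVA


def anova_2x2(values, factor_a, factor_b) -> dict[str, TestResult]:
    """Balanced two-way ANOVA with interaction for a 2x2 design.

    Returns TestResults keyed ``factor_a``, ``factor_b``, ``interaction``,
    each with df = 1 and error df = N - 4.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise DataError("values and factor labels must have equal length")
    la, lb = np.unique(fa), np.unique(fb)
    if la.size != 2 or lb.size != 2:
        raise DataError("anova_2x2 requires exactly two levels per factor")
    cells = {}
    for a in la:
        for b in lb:
            cells[(a, b)] = y[(fa == a) & (fb == b)]
    sizes = {k: v.size for k, v in cells.items()}
    n = next(iter(sizes.values()))
    if n < 2 or any(s != n for s in sizes.values()):
        raise DataError("anova_2x2 requires a balanced design with >=2 per cell")
    total_n = y.size
    grand = y.mean()
    mean_a = {a: y[fa == a].mean() for a in la}
    mean_b = {b: y[fb == b].mean() for b in lb}
    cell_mean = {k: v.mean() for k, v in cells.items()}
    ss_a = 2 * n * sum((mean_a[a] - grand) ** 2 for a in la)
    ss_b = 2 * n * sum((mean_b[b] - grand) ** 2 for b in lb)
    ss_ab = n * sum(
        (cell_mean[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in la for b in lb
    )
    ss_err = sum(((v - cell_mean[k]) ** 2).sum() for k, v in cells.items())
    df_err = total_n - 4
    ms_err = ss_err / df_err

    def result(ss: float, name: str) -> TestResult:
        if ms_err == 0.0:
            if ss == 0.0:
                return TestResult(0.0, 1.0, f"anova_2x2:{name}", df=1,
                                  n_effective=total_n)
            return TestResult(np.inf, 0.0, f"anova_2x2:{name}", df=1,
                              n_effective=total_n, flag="zero error variance")
        f = ss / ms_err
        p = float(sps.f.sf(f, 1, df_err))
        return TestResult(float(f), p, f"anova_2x2:{name}", df=1,
                          n_effective=total_n,
                          extra={"ss": float(ss), "df_error": df_err,
                                 "ms_error": float(ms_err)})

    return {
        "factor_a": result(ss_a, "factor_a"),
        "factor_b": result(ss_b, "factor_b"),
        "interaction": result(ss_ab, "interaction"),
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def signed_rank_p(w: float, n_r: int, tie_counts=()) -> float:
    """Two-sided p for signed-rank statistic W with N_r nonzero differences.

    Normal approximation with a 0.5 continuity correction toward the null
    mean and tie-corrected variance:

        mu    = N_r (N_r + 1) / 4
        var   = N_r (N_r + 1)(2 N_r + 1) / 24 - sum(t^3 - t) / 48
        z     = (|W - mu| - 0.5) / sqrt(var)
        p     = 2 * Phi(-z), capped at 1
    """
    if n_r < 1:
        raise DataError("signed_rank_p requires N_r >= 1")
    mu = n_r * (n_r + 1) / 4.0
    var = n_r * (n_r + 1) * (2 * n_r + 1) / 24.0
    var -= sum(t**3 - t for t in tie_counts) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


def _signed_rank_exact_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating all sign assignments."""
    n = ranks.size
    dist: dict[float, int] = {0.0: 1}
    for r in ranks:
        nxt: dict[float, int] = {}
        for s, c in dist.items():
            nxt[s] = nxt.get(s, 0) + c
            nxt[s + r] = nxt.get(s + r, 0) + c
        dist = nxt
    total = 2**n
    mu = ranks.sum() / 2.0
    dev = abs(w - mu)
    count = sum(c for s, c in dist.items() if abs(s - mu) >= dev - 1e-12)
    return min(1.0, count / total)


def wilcoxon_signed_rank(diffs, method: str = "approx") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (N_r counts the rest); |differences| are
    ranked with average ranks on ties; W is the sum of ranks of positive
    differences. ``method='approx'`` (default) is the continuity-corrected
    normal approximation; ``method='exact'`` enumerates sign assignments
    (suitable for small N_r).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n_r = d.size
    if n_r == 0:
        return TestResult(np.nan, None, "wilcoxon_signed_rank",
                          n_effective=0, flag="all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    if method == "approx":
        p = signed_rank_p(w, n_r, tie_counts=tie_counts[tie_counts > 1])
    elif method == "exact":
        p = _signed_rank_exact_p(w, ranks)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(w, p, f"wilcoxon_signed_rank:{method}", n_effective=n_r,
                      extra={"W": w, "N_r": n_r})


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> TestResult:
    """Two-sided rank-sum test of two independent samples.

    Exact by full enumeration when n1 + n2 <= ``exact_limit`` and there
    are no ties; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size == 0 or ay.size == 0:
        raise DataError("wilcoxon_rank_sum requires non-empty samples")
    combined = np.concatenate([ax, ay])
    if np.ptp(combined) == 0.0:
        return TestResult(ax.size * ay.size / 2.0, 1.0,
                          "wilcoxon_rank_sum:degenerate",
                          n_effective=combined.size)
    has_ties = np.unique(combined).size < combined.size
    small = combined.size <= exact_limit
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(ax, ay, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"wilcoxon_rank_sum:{method}",
                      n_effective=combined.size)


def rank_sum_enumeration_p(x, y) -> float:
    """Brute-force exact two-sided rank-sum p by enumerating assignments.

    Independent oracle for :func:`wilcoxon_rank_sum`; only feasible for
    tiny samples.
    """
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    pooled = np.concatenate([ax, ay])
    ranks = sps.rankdata(pooled)
    n1 = ax.size
    obs = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_i = min_{j>=i} p_(j) m / j."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DataError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(arr)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t transform."""
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size != ay.size or ax.size < 3:
        raise DataError("pearson_r requires paired samples with n >= 3")
    if np.ptp(ax) == 0.0 or np.ptp(ay) == 0.0:
        return TestResult(np.nan, None, "pearson_r", n_effective=ax.size,
                          flag="zero variance")
    r, p = sps.pearsonr(ax, ay)
    return TestResult(float(r), float(p), "pearson_r",
                      df=ax.size - 2, n_effective=ax.size)
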