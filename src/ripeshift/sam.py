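"""Significance Analysis of Microarrays (SAM), implemented from first principles.

Two-class unpaired statistic (Tusher-style)::

    d_i = (mean_B - mean_A) / (s_i + s0)
    s_i = sqrt((1/n_A + 1/n_B) * (SS_A + SS_B) / (n_A + n_B - 2))

Multiclass (K >= 3 groups) F-like statistic::

    d_i = r_i / (s_i + s0)
    r_i = sqrt((sum_k 1/n_k) * sum_k n_k (xbar_ik - xbar_i)^2)
    s_i = sqrt((sum_k 1/n_k) / (n - K) * sum_k SS_ik)

which for K = 2 reduces exactly to |d_i| of the two-class form, so the two
statistics induce the same ranking on a two-group design.

The null is built by permuting sample labels: exhaustively when the number of
distinct assignments is small, otherwise by uniform sampling with a seed.  The
significance band is the classic delta procedure: genes whose sorted statistic
departs from the permutation-expected order statistic by more than delta are
called, the median permuted exceedance count estimates false positives, and
delta is tuned on a fixed grid to the smallest value achieving the target
set-level FDR.

All statistics are computed on log2 intensities; the fold-change filter of the
combined calls operates on the linear scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, fold_change


@dataclass
class SAMConfig:
    n_permutations: int = 1000
    exhaustive_if_fewer: bool = True
    s0_method: str = "tusher_percentile"  # or "median_s", "fixed"
    s0_value: float | None = None
    fdr_target: float = 0.02
    delta_grid_step: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_target < 1.0:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.s0_method not in ("tusher_percentile", "median_s", "fixed"):
            raise ValueError(f"unknown s0_method {self.s0_method!r}")
        if self.s0_method == "fixed" and self.s0_value is None:
            raise ValueError("s0_method='fixed' requires s0_value")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _twoclass_parts(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Numerator (mean_B - mean_A) and pooled SE s_i, per gene (rows)."""
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ssa = ((xa - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return mb - ma, s


def d_statistic_twoclass(xa: np.ndarray, xb: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-class unpaired SAM statistic and the gene-wise pooled SE.

    Genes with zero pooled variance and s0 = 0 yield +/-inf (or NaN for a
    zero numerator); callers exclude non-finite rows from ranking.
    """
    numer, s = _twoclass_parts(np.asarray(xa, float), np.asarray(xb, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = numer / (s + s0)
    d = np.where((numer == 0) & (s + s0 == 0), 0.0, d)
    return d, s


def _multiclass_parts(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    ns = [g.shape[1] for g in groups]
    if any(n < 2 for n in ns):
        raise ValueError("each group needs >= 2 replicates")
    n_tot, k = sum(ns), len(groups)
    inv_sum = sum(1.0 / n for n in ns)
    all_x = np.concatenate(groups, axis=1)
    grand = all_x.mean(axis=1)
    between = np.zeros(grand.shape)
    ss_within = np.zeros(grand.shape)
    for g, n in zip(groups, ns):
        m = g.mean(axis=1)
        between += n * (m - grand) ** 2
        ss_within += ((g - m[:, None]) ** 2).sum(axis=1)
    r = np.sqrt(inv_sum * between)
    s = np.sqrt(inv_sum / (n_tot - k) * ss_within)
    return r, s


def multiclass_statistic(groups: list[np.ndarray], s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative multiclass SAM statistic (F-like) and gene-wise SE."""
    r, s = _multiclass_parts([np.asarray(g, float) for g in groups])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / (s + s0)
    d = np.where((r == 0) & (s + s0 == 0), 0.0, d)
    return d, s


def estimate_s0(numer: np.ndarray, s: np.ndarray, config: SAMConfig) -> float:
    """Fudge factor from the configured rule.

    ``tusher_percentile``: candidate s0 values are percentiles of s; pick the
    one minimizing the coefficient of variation of the median absolute
    deviation of d across 100 windows of s (the Tusher/samr objective).
    """
    s = np.asarray(s, float)
    if config.s0_method == "fixed":
        return float(config.s0_value)
    if config.s0_method == "median_s":
        return float(np.median(s))
    finite = np.isfinite(numer) & np.isfinite(s)
    numer, s = numer[finite], s[finite]
    if s.size < 10 or np.allclose(s, s[0]):
        return float(np.median(s)) if s.size else 0.0
    candidates = np.percentile(s, np.arange(0, 101, 5))
    qs = np.quantile(s, np.linspace(0, 1, 101))
    window = np.clip(np.searchsorted(qs[1:-1], s, side="right"), 0, 99)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numer / (s + s0)
        mads = []
        for w in range(100):
            dw = d[window == w]
            if dw.size:
                mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def _distinct_label_permutations(ns: list[int]):
    """All distinct assignments of n = sum(ns) samples into ordered groups.

    Yields tuples of group indices of length n; the count is the multinomial
    coefficient n! / prod(n_k!).
    """
    labels = [k for k, n in enumerate(ns) for _ in range(n)]
    seen_first = sorted(labels)
    # lexicographic next-permutation over the multiset
    cur = list(seen_first)
    while True:
        yield tuple(cur)
        i = len(cur) - 2
        while i >= 0 and cur[i] >= cur[i + 1]:
            i -= 1
        if i < 0:
            return
        j = len(cur) - 1
        while cur[j] <= cur[i]:
            j -= 1
        cur[i], cur[j] = cur[j], cur[i]
        cur[i + 1:] = reversed(cur[i + 1:])


def count_distinct_assignments(ns: list[int]) -> int:
    n = sum(ns)
    c = math.factorial(n)
    for k in ns:
        c //= math.factorial(k)
    return c


@dataclass
class PermutationNull:
    """Sorted permuted statistics (B x p) and expected order statistics."""

    perm_sorted: np.ndarray           # each row ascending
    expected_sorted: np.ndarray       # rank-wise mean over permutations
    exhaustive: bool
    n_permutations: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_permutations = self.perm_sorted.shape[0]


def permutation_null(
    X: np.ndarray,
    group_sizes: list[int],
    s0: float,
    config: SAMConfig,
    two_class: bool | None = None,
) -> PermutationNull:
    """Permute sample labels and collect sorted null statistics.

    ``X`` is genes x samples (log2) with columns ordered by group.  When the
    number of distinct label assignments is at most ``n_permutations`` and
    ``exhaustive_if_fewer`` is set, every distinct assignment is used exactly
    once; otherwise assignments are drawn uniformly with the configured seed.
    """
    X = np.asarray(X, float)
    n = X.shape[1]
    if sum(group_sizes) != n:
        raise ValueError("group sizes do not match number of columns")
    if two_class is None:
        two_class = len(group_sizes) == 2
    total = count_distinct_assignments(group_sizes)
    use_exhaustive = config.exhaustive_if_fewer and total <= config.n_permutations

    if use_exhaustive:
        assignments = np.array(list(_distinct_label_permutations(group_sizes)))
    else:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A17]))
        base = np.array([k for k, m in enumerate(group_sizes) for _ in range(m)])
        assignments = np.array([rng.permutation(base) for _ in range(config.n_permutations)])

    stats = np.empty((assignments.shape[0], X.shape[0]))
    for b, lab in enumerate(assignments):
        groups = [X[:, lab == k] for k in range(len(group_sizes))]
        if two_class:
            d, _ = d_statistic_twoclass(groups[0], groups[1], s0)
        else:
            d, _ = multiclass_statistic(groups, s0)
        finite = np.isfinite(d)
        if not finite.all():
            # a degenerate labeling can zero the within-group variance at
            # s0 = 0; clamp to the row's finite extremes to keep ranks usable
            hi = d[finite].max() if finite.any() else 0.0
            lo = d[finite].min() if finite.any() else 0.0
            d = np.where(np.isposinf(d), hi, d)
            d = np.where(np.isneginf(d), lo, d)
            d = np.where(np.isnan(d), 0.0, d)
        stats[b] = np.sort(d)
    return PermutationNull(
        perm_sorted=stats,
        expected_sorted=stats.mean(axis=0),
        exhaustive=use_exhaustive,
    )


# ---------------------------------------------------------------------------
# Delta calling
# ---------------------------------------------------------------------------


@dataclass
class SAMCall:
    delta: float
    cut_up: float
    cut_low: float
    called: np.ndarray            # boolean per gene, original order
    n_called: int
    est_false_positives: float    # median over permutations
    est_fdr: float
    unattainable: bool
    expected_d: np.ndarray        # per gene, aligned by rank


def _cutoffs_for_delta(
    d_sorted: np.ndarray, dbar: np.ndarray, delta: float, one_sided: bool
) -> tuple[float, float]:
    diff = d_sorted - dbar
    origin = 0 if one_sided else int(np.searchsorted(d_sorted, 0.0))
    cut_up = np.inf
    up = np.flatnonzero(diff[origin:] >= delta)
    if up.size:
        cut_up = d_sorted[origin + up[0]]
    cut_low = -np.inf
    if not one_sided and origin > 0:
        down = np.flatnonzero(diff[:origin][::-1] <= -delta)
        if down.size:
            cut_low = d_sorted[origin - 1 - down[0]]
    return cut_up, cut_low


def call_significant(
    d: np.ndarray,
    null: PermutationNull,
    config: SAMConfig,
    one_sided: bool = False,
) -> SAMCall:
    """Tune delta to the target FDR and call genes outside the band.

    Non-finite statistics (zero-variance genes with s0 = 0) are excluded from
    ranking with a warning and never called.
    """
    d = np.asarray(d, float)
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} gene(s) with non-finite statistic excluded from SAM ranking",
            RuntimeWarning,
        )
    dv = d[finite]
    order = np.argsort(dv, kind="stable")
    d_sorted = dv[order]
    dbar = null.expected_sorted
    if dbar.shape[0] != d_sorted.shape[0]:
        raise ValueError("null was computed for a different number of genes")

    max_delta = float(np.max(np.abs(d_sorted - dbar))) if d_sorted.size else 0.0
    step = config.delta_grid_step
    grid = np.arange(step, max_delta + step, step)

    perm = null.perm_sorted
    B = perm.shape[0]
    best = None
    for delta in grid:
        cut_up, cut_low = _cutoffs_for_delta(d_sorted, dbar, float(delta), one_sided)
        called_mask = (d_sorted >= cut_up) | (d_sorted <= cut_low)
        n_called = int(called_mask.sum())
        if n_called == 0:
            continue
        fp = np.empty(B)
        for b in range(B):
            row = perm[b]
            n_up = row.size - np.searchsorted(row, cut_up, side="left")
            n_low = np.searchsorted(row, cut_low, side="right") if np.isfinite(cut_low) else 0
            fp[b] = n_up + n_low
        med_fp = float(np.median(fp))
        fdr = med_fp / n_called
        if fdr <= config.fdr_target:
            best = (float(delta), cut_up, cut_low, called_mask, n_called, med_fp, fdr)
            break

    expected_full = np.full(d.shape, np.nan)
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    expected_full[finite] = dbar[ranks]

    called_full = np.zeros(d.shape, bool)
    if best is None:
        return SAMCall(
            delta=math.inf, cut_up=math.inf, cut_low=-math.inf, called=called_full,
            n_called=0, est_false_positives=0.0, est_fdr=0.0, unattainable=True,
            expected_d=expected_full,
        )
    delta, cut_up, cut_low, called_mask, n_called, med_fp, fdr = best
    idx = np.flatnonzero(finite)
    called_full[idx[order]] = called_mask
    return SAMCall(
        delta=delta, cut_up=cut_up, cut_low=cut_low, called=called_full,
        n_called=n_called, est_false_positives=med_fp, est_fdr=fdr,
        unattainable=False, expected_d=expected_full,
    )


# ---------------------------------------------------------------------------
# High-level entry points on ExpressionMatrix
# ---------------------------------------------------------------------------


def _resolve_s0(numer: np.ndarray, s: np.ndarray, config: SAMConfig) -> float:
    return estimate_s0(numer, s, config)


def _expand_call(call: SAMCall, finite: np.ndarray) -> SAMCall:
    """Re-embed a call computed on the finite-statistic subset."""
    if finite.all():
        return call
    called = np.zeros(finite.shape, bool)
    called[finite] = call.called
    expected = np.full(finite.shape, np.nan)
    expected[finite] = call.expected_d
    return SAMCall(
        delta=call.delta, cut_up=call.cut_up, cut_low=call.cut_low, called=called,
        n_called=call.n_called, est_false_positives=call.est_false_positives,
        est_fdr=call.est_fdr, unattainable=call.unattainable, expected_d=expected,
    )


def sam_twoclass(
    matrix: ExpressionMatrix,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    config: SAMConfig,
    genes=None,
) -> tuple[pd.DataFrame, SAMCall, float]:
    """Two-class SAM between (treatment, stage) groups on log2 intensities."""
    sub = matrix if genes is None else matrix.subset_genes(genes)
    xa = np.log2(sub.group_values(*group_a).to_numpy(float))
    xb = np.log2(sub.group_values(*group_b).to_numpy(float))
    numer, s = _twoclass_parts(xa, xb)
    s0 = _resolve_s0(numer, s, config)
    d, _ = d_statistic_twoclass(xa, xb, s0)
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} gene(s) with non-finite statistic excluded from SAM",
            RuntimeWarning,
        )
    X = np.concatenate([xa, xb], axis=1)[finite]
    null = permutation_null(X, [xa.shape[1], xb.shape[1]], s0, config)
    call = call_significant(d[finite], null, config, one_sided=False)
    call = _expand_call(call, finite)
    table = pd.DataFrame({"d": d, "expected_d": call.expected_d, "s": s},
                         index=sub.genes)
    return table, call, s0


def sam_pairwise(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str, str],
    fc_threshold: float = 2.0,
    config: SAMConfig | None = None,
    genes=None,
) -> pd.DataFrame:
    """Pairwise DE at one stage: SAM-significant AND |FC| >= fc_threshold.

    ``contrast`` is (treatment A, treatment B, stage); fold change is B over A
    on the linear scale and direction comes from its sign.  Returns a DETable
    with columns d, expected_d, fc, direction, called (gene-indexed); ``called``
    marks the combined DE set.
    """
    config = config or SAMConfig()
    t_a, t_b, stage = contrast
    for t in (t_a, t_b):
        matrix.group_samples(t, stage)  # raises KeyError for unknown contrast
    table, call, _ = sam_twoclass(matrix, (t_a, stage), (t_b, stage), config, genes=genes)
    sub = matrix if genes is None else matrix.subset_genes(genes)
    fc = fold_change(sub, (t_a, stage), (t_b, stage))
    de = pd.DataFrame({
        "d": table["d"],
        "expected_d": table["expected_d"],
        "fc": fc["fc"],
        "direction": fc["direction"],
        "called": call.called & (fc["fc"].abs() >= fc_threshold),
    })
    de.attrs["stage"] = stage
    de.attrs["contrast"] = contrast
    de.attrs["sam_call"] = call
    return de


def sam_multiclass_modulated(
    matrix: ExpressionMatrix,
    treatment: str,
    stages: list[str] | None = None,
    fc_threshold: float = 2.0,
    config: SAMConfig | None = None,
    genes=None,
) -> pd.DataFrame:
    """Stage-modulated genes within one treatment.

    Modulated = multiclass-SAM-significant AND |FC| >= fc_threshold for at
    least one later stage against the first (baseline) stage.  Returns a table
    with the statistic, the per-stage FCs and the ``modulated`` flag.
    """
    config = config or SAMConfig()
    sub = matrix if genes is None else matrix.subset_genes(genes)
    stages = list(stages) if stages is not None else [
        s for s in sub.stages if any(
            (sub.meta["treatment"] == treatment) & (sub.meta["stage"] == s)
        )
    ]
    if len(stages) < 3:
        raise ValueError("multiclass comparison needs >= 3 stages")
    groups = [np.log2(sub.group_values(treatment, s).to_numpy(float)) for s in stages]
    r, s_arr = _multiclass_parts(groups)
    s0 = _resolve_s0(r, s_arr, config)
    d, _ = multiclass_statistic(groups, s0)
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} gene(s) with non-finite statistic excluded from SAM",
            RuntimeWarning,
        )
    X = np.concatenate(groups, axis=1)[finite]
    null = permutation_null(X, [g.shape[1] for g in groups], s0, config, two_class=False)
    call = call_significant(d[finite], null, config, one_sided=True)
    call = _expand_call(call, finite)
    out = pd.DataFrame({"d": d, "expected_d": call.expected_d}, index=sub.genes)
    base = stages[0]
    fc_pass = np.zeros(len(out), bool)
    for stage in stages[1:]:
        fc = fold_change(sub, (treatment, base), (treatment, stage))["fc"]
        out[f"fc_{stage}_{base}"] = fc
        fc_pass |= (fc.abs() >= fc_threshold).to_numpy()
    out["modulated"] = call.called & fc_pass
    out.attrs["sam_call"] = call
    out.attrs["treatment"] = treatment
    out.attrs["stages"] = stages
    return out
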