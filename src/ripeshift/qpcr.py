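"""Relative qPCR quantification with reaction-specific efficiencies.

Amplification efficiency E (per-cycle amplification factor, in (1, 2]) is
estimated per well by the window-of-linearity approach: fit log(fluorescence)
against cycle over the sliding window with the best R² inside the exponential
phase, after baseline correction.  Quantification cycles (Ct) come from
log-linear interpolation of the first threshold crossing.  Relative
expression against a baseline stage uses the efficiency-corrected ratio

    R = E_target ** dCt_target / E_ref ** dCt_ref,

with dCt = Ct(baseline) - Ct(stage) and a reference gene of constant
expression (e.g. EF1).  Replicate spread is summarized as the standard error
of per-replicate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoExponentialPhaseError(ValueError):
    """No sliding window reached the required log-linearity."""


@dataclass
class EfficiencyEstimate:
    E: float                    # per-cycle amplification factor in (1, 2]
    window: tuple[int, int]     # first and last cycle of the fitted window
    r_squared: float
    clipped: bool = False


def baseline_correct(fluorescence: np.ndarray, n_baseline: int = 5) -> np.ndarray:
    """Subtract the mean of the first ``n_baseline`` cycles."""
    f = np.asarray(fluorescence, float)
    return f - f[:n_baseline].mean()


def estimate_efficiency(
    cycles: np.ndarray,
    fluorescence: np.ndarray,
    min_window: int = 4,
    r2_min: float = 0.998,
    baseline_cycles: int = 5,
) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate from a raw amplification curve.

    All windows of length >= ``min_window`` over the positive part of the
    baseline-corrected curve are fit as log10(F) vs cycle; the window with the
    highest R² wins (ties: longest window, then earliest start).  E =
    10**slope, clipped into (1, 2] with a warning flag when outside.
    """
    cycles = np.asarray(cycles, float)
    f = np.asarray(fluorescence, float)
    if cycles.size < 10:
        raise ValueError("need >= 10 cycles")
    if np.any(np.diff(cycles) <= 0):
        raise ValueError("cycles must be strictly increasing")
    corrected = baseline_correct(f, baseline_cycles) if baseline_cycles else f
    pos = corrected > 0
    logf = np.full_like(corrected, np.nan)
    logf[pos] = np.log10(corrected[pos])

    n = cycles.size
    # prefix sums over the curve make every window's regression O(1)
    x = cycles
    y = np.where(pos, logf, 0.0)
    cx = np.concatenate([[0.0], np.cumsum(np.where(pos, x, 0.0))])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(np.where(pos, x * x, 0.0))])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(np.where(pos, x * y, 0.0))])

    best: tuple[float, int, int, float] | None = None  # (r2, length, start, slope)
    for start in range(n):
        if not pos[start]:
            continue
        for end in range(start + min_window, n + 1):
            if not pos[end - 1]:
                break
            m = end - start
            sx, sy = cx[end] - cx[start], cy[end] - cy[start]
            sxx, syy = cxx[end] - cxx[start], cyy[end] - cyy[start]
            sxy = cxy[end] - cxy[start]
            var_x = sxx - sx * sx / m
            var_y = syy - sy * sy / m
            cov = sxy - sx * sy / m
            if var_x <= 0:
                continue
            slope = cov / var_x
            r2 = cov * cov / (var_x * var_y) if var_y > 0 else 0.0
            if r2 < r2_min:
                continue
            key = (round(r2, 12), m, -start)
            if best is None or key > (round(best[0], 12), best[1], -best[2]):
                best = (r2, m, start, slope)
    if best is None:
        raise NoExponentialPhaseError("no exponential phase: no window reached r2_min")
    r2, length, start, slope = best
    E = float(10.0 ** slope)
    clipped = False
    if E > 2.0:
        E, clipped = 2.0, True
    elif E <= 1.0:
        E, clipped = 1.0 + 1e-9, True
    return EfficiencyEstimate(
        E=E, window=(int(cycles[start]), int(cycles[start + length - 1])),
        r_squared=r2, clipped=clipped,
    )


def compute_ct(cycles: np.ndarray, fluorescence: np.ndarray, threshold: float) -> float:
    """Fractional cycle of the first threshold crossing.

    Interpolation is linear in log(fluorescence), so for an exact exponential
    F_c = F0 * E**c the result is exactly log_E(threshold / F0), and doubling
    the starting amount lowers Ct by exactly log_E(2).
    """
    cycles = np.asarray(cycles, float)
    f = np.asarray(fluorescence, float)
    above = f >= threshold
    if not above.any():
        raise ValueError("curve never crosses the threshold")
    i = int(np.argmax(above))
    if i == 0:
        raise ValueError("threshold is below the curve's starting fluorescence")
    f0, f1 = f[i - 1], f[i]
    if f0 <= 0 or f1 <= 0 or threshold <= 0:
        frac = (threshold - f0) / (f1 - f0)  # linear fallback off the log scale
    else:
        frac = (np.log(threshold) - np.log(f0)) / (np.log(f1) - np.log(f0))
    return float(cycles[i - 1] + frac * (cycles[i] - cycles[i - 1]))


def pfaffl_ratio(E_target: float, dCt_target: float, E_ref: float, dCt_ref: float) -> float:
    """Efficiency-corrected relative expression ratio."""
    for E in (E_target, E_ref):
        if not 1.0 < E <= 2.0:
            raise ValueError(f"efficiency {E} outside (1, 2]")
    return float(E_target ** dCt_target / E_ref ** dCt_ref)


def ratio_se(ratios) -> tuple[float, float]:
    """Mean and standard error of per-replicate ratios (>= 2 values)."""
    r = np.asarray(list(ratios), float)
    if r.size < 2:
        raise ValueError("need >= 2 replicate ratios")
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(r.size))


# ---------------------------------------------------------------------------
# Plate-level quantification
# ---------------------------------------------------------------------------


def _well_meta(well: str) -> tuple[str, str, int]:
    gene, stage, rep = well.rsplit("_", 2)
    return gene, stage, int(rep)


def quantify_plate(
    plate: pd.DataFrame,
    reference: str,
    baseline_stage: str = "BV",
    threshold: float | None = None,
    min_window: int = 4,
    r2_min: float = 0.998,
) -> pd.DataFrame:
    """Pfaffl quantification of a long-format plate.

    ``plate`` has columns gene, well, cycle, fluorescence; well IDs encode
    ``gene_stage_replicate``.  Efficiency is per gene (mean of well-level
    window-of-linearity estimates).  Ratios are computed per biological
    replicate (pairing baseline and test wells by replicate number) and
    summarized as mean +/- SE.  Returns a table indexed by (gene, stage) with
    ratio, se, E_target, E_ref.
    """
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for well, grp in plate.groupby("well", sort=False):
        grp = grp.sort_values("cycle")
        curves[well] = (grp["cycle"].to_numpy(float), grp["fluorescence"].to_numpy(float))

    if threshold is None:
        maxima = [baseline_correct(f).max() for _, f in curves.values()]
        threshold = 0.1 * float(np.median(maxima))

    eff: dict[str, list[float]] = {}
    cts: dict[tuple[str, str, int], float] = {}
    for well, (cyc, f) in curves.items():
        gene, stage, rep = _well_meta(well)
        est = estimate_efficiency(cyc, f, min_window=min_window, r2_min=r2_min)
        eff.setdefault(gene, []).append(est.E)
        cts[(gene, stage, rep)] = compute_ct(cyc, baseline_correct(f), threshold)
    E_gene = {g: float(np.mean(v)) for g, v in eff.items()}
    if reference not in E_gene:
        raise KeyError(f"reference gene {reference!r} not on the plate")

    stages = sorted({s for (_, s, _) in cts}, key=lambda s: s != baseline_stage)
    rows = []
    for gene in sorted(E_gene):
        if gene == reference:
            continue
        for stage in stages:
            reps = sorted(r for (g, s, r) in cts if g == gene and s == stage)
            ratios = []
            for rep in reps:
                d_ct_t = cts[(gene, baseline_stage, rep)] - cts[(gene, stage, rep)]
                d_ct_r = cts[(reference, baseline_stage, rep)] - cts[(reference, stage, rep)]
                ratios.append(pfaffl_ratio(E_gene[gene], d_ct_t, E_gene[reference], d_ct_r))
            mean, se = ratio_se(ratios) if len(ratios) > 1 else (float(ratios[0]), 0.0)
            rows.append({
                "gene": gene, "stage": stage, "ratio": mean, "se": se,
                "E_target": E_gene[gene], "E_ref": E_gene[reference],
            })
    return pd.DataFrame(rows).set_index(["gene", "stage"])
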