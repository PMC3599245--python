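"""Synthetic data with the statistical structure of a defoliation time course.

The expression simulator plants, on the log2 scale, a control "ripening
program" (genes down- or up-modulated between the beginning and end of
veraison), treatment copies of that program shifted one stage later (the
delayed-ripening signature), genes genuinely modulated by one treatment
independent of the program, silent genes below the negative-control floor,
and flat expressed genes.  Replicate noise is additive Normal on the log2
scale (multiplicative on intensities), so planted fold changes are exact in
the noise-free limit.

Also provided: an idealized qPCR plate simulator (exponential amplification
with plateau) and a timestamped berry-skin temperature series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, NegativeControls

PROGRAM_CLASSES = ("program-down", "program-up")
DELAYED_CLASSES = ("delayed-in-PB", "delayed-in-V")
GENUINE_CLASSES = ("genuine-up-PB", "genuine-down-PB", "genuine-up-V", "genuine-down-V")
ALL_CLASSES = PROGRAM_CLASSES + DELAYED_CLASSES + GENUINE_CLASSES + ("silent", "flat")


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Design of a simulated three-treatment, three-stage berry experiment.

    Fractions are fractions of ``n_genes``; each gene receives exactly one
    truth class.  ``frac_genuine_up``/``frac_genuine_down`` apply per
    treatment (PB and V each get that fraction of genes).  The remainder
    after all planted classes are flat expressed genes.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    treatments: tuple[str, ...] = ("C", "PB", "V")
    stages: tuple[str, ...] = ("BV", "EV", "H")
    frac_program_down: float = 0.15
    frac_program_up: float = 0.15
    frac_delayed_PB: float = 0.05
    frac_delayed_V: float = 0.05
    frac_genuine_up: float = 0.025
    frac_genuine_down: float = 0.025
    frac_silent: float = 0.10
    effect_size: float = 2.0       # |log2 FC| of every planted modulation
    noise_sd: float = 0.2          # replicate SD on the log2 scale
    negctrl_mean: float = 100.0    # linear fluorescence
    negctrl_sd: float = 0.5        # log2-scale SD of control probes
    n_negctrl_probes: int = 200
    baseline_log2_range: tuple[float, float] = (8.0, 13.0)
    silent_margin_log2: float = 2.0  # silent genes sit this far below the control mean
    shared_heat_stress: bool = False  # genuine-up genes shared by PB and V
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.class_fractions()
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"fraction {name}={f} outside [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigError(f"class fractions sum to {sum(fracs.values()):.3f} > 1")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("stages must be unique")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def class_fractions(self) -> dict[str, float]:
        return {
            "program-down": self.frac_program_down,
            "program-up": self.frac_program_up,
            "delayed-in-PB": self.frac_delayed_PB,
            "delayed-in-V": self.frac_delayed_V,
            "genuine-up-PB": self.frac_genuine_up,
            "genuine-down-PB": self.frac_genuine_down,
            "genuine-up-V": self.frac_genuine_up,
            "genuine-down-V": self.frac_genuine_down,
            "silent": self.frac_silent,
        }

    def class_counts(self) -> dict[str, int]:
        """Deterministic fraction-to-count rule: floor each class, remainder flat."""
        counts = {name: int(math.floor(f * self.n_genes)) for name, f in self.class_fractions().items()}
        counts["flat"] = self.n_genes - sum(counts.values())
        return counts


def _template_for(
    label: str, gene_idx: int, base: float, effect: float, stages: tuple[str, ...],
    treatments: tuple[str, ...], silent_level: float,
) -> dict[str, np.ndarray]:
    """Planted mean log2 profile per condition, indexed over stages.

    The ripening program runs in every treatment; "delayed" means the control's
    BV->EV change occurs only EV->H in the shifted treatment.  Alternating gene
    index picks the direction of delayed modulation (half down, half up).
    """
    n = len(stages)
    flat = np.full(n, base)
    down = np.array([base] + [base - effect] * (n - 1))
    up = np.array([base] + [base + effect] * (n - 1))
    down_late = np.array([base] * (n - 1) + [base - effect])
    up_late = np.array([base] * (n - 1) + [base + effect])
    per_cond = {t: flat.copy() for t in treatments}
    if label == "program-down":
        per_cond = {t: down.copy() for t in treatments}
    elif label == "program-up":
        per_cond = {t: up.copy() for t in treatments}
    elif label in ("delayed-in-PB", "delayed-in-V"):
        shifted = "PB" if label.endswith("PB") else "V"
        sign_down = gene_idx % 2 == 0
        early, late = (down, down_late) if sign_down else (up, up_late)
        per_cond = {t: (late.copy() if t == shifted else early.copy()) for t in treatments}
    elif label.startswith("genuine-"):
        _, direction, target = label.split("-")
        prof = up if direction == "up" else down
        per_cond = {t: (prof.copy() if t == target else flat.copy()) for t in treatments}
    elif label == "silent":
        per_cond = {t: np.full(n, silent_level) for t in treatments}
    return per_cond


def _template_tag(profile: np.ndarray, base: float, stages: tuple[str, ...]) -> str:
    """Human-readable template summary, e.g. ``down@EV`` or ``flat``."""
    diffs = profile[1:] - profile[0]
    if np.allclose(diffs, 0):
        return "flat"
    onset = int(np.flatnonzero(~np.isclose(diffs, 0))[0]) + 1
    direction = "down" if diffs[np.flatnonzero(~np.isclose(diffs, 0))[0]] < 0 else "up"
    return f"{direction}@{stages[onset]}"


def simulate_experiment(
    config: SimConfig,
) -> tuple[ExpressionMatrix, NegativeControls, pd.DataFrame]:
    """Generate an expression matrix, negative controls and the truth table.

    Returns
    -------
    matrix, controls, truth
        ``truth`` has one row per gene: ``label``, ``log2_effect`` and one
        ``template_<condition>`` column per treatment summarizing the planted
        profile (``flat``, ``silent``, ``down@EV``, ``up@H``, ...).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    counts = config.class_counts()
    labels: list[str] = []
    for name in (*PROGRAM_CLASSES, *DELAYED_CLASSES, *GENUINE_CLASSES, "silent", "flat"):
        labels.extend([name] * counts[name])
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    lo, hi = config.baseline_log2_range
    bases = rng.uniform(lo, hi, size=config.n_genes)
    silent_level = math.log2(config.negctrl_mean) - config.silent_margin_log2

    samples = [
        f"{t}_{s}_{r}"
        for t in config.treatments
        for s in config.stages
        for r in range(1, config.n_replicates + 1)
    ]
    n_samples = len(samples)
    sample_cond = [s.split("_")[0] for s in samples]
    sample_stage_idx = [config.stages.index(s.split("_")[1]) for s in samples]

    log2_means = np.empty((config.n_genes, n_samples))
    truth_rows = []
    for i, (gene, label) in enumerate(zip(genes, labels)):
        per_cond = _template_for(
            label, i, bases[i], config.effect_size, config.stages,
            config.treatments, silent_level,
        )
        for j in range(n_samples):
            log2_means[i, j] = per_cond[sample_cond[j]][sample_stage_idx[j]]
        row = {"gene": gene, "label": label,
               "log2_effect": 0.0 if label in ("silent", "flat") else config.effect_size}
        for t in config.treatments:
            tag = "silent" if label == "silent" else _template_tag(per_cond[t], bases[i], config.stages)
            row[f"template_{t}"] = tag
        truth_rows.append(row)

    noise = rng.normal(0.0, config.noise_sd, size=log2_means.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(
        np.exp2(log2_means + noise), index=pd.Index(genes, name="gene"), columns=samples
    )
    matrix = ExpressionMatrix(values)

    ctrl_log2_mean = math.log2(config.negctrl_mean)
    controls = NegativeControls({
        s: np.exp2(rng.normal(ctrl_log2_mean, config.negctrl_sd, size=config.n_negctrl_probes))
        for s in samples
    })
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return matrix, controls, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

REFERENCE_GENE = "REF"


def simulate_qpcr_plate(
    n_genes: int,
    true_E: float | np.ndarray = 1.9,
    true_ratio: float | np.ndarray = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_cycles: int = 40,
    n_replicates: int = 3,
    f0: float = 1e-3,
    plateau: float = 1e4,
    stages: tuple[str, str] = ("BV", "EV"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an idealized qPCR plate in long format.

    Each target gene is amplified at a baseline stage and a test stage, in
    ``n_replicates`` wells each, alongside a reference gene with constant
    starting amount.  Curves follow ``F_c = F0 * E**c`` capped at ``plateau``;
    multiplicative log-normal noise of SD ``noise_sd`` is applied per reading.
    ``true_ratio`` scales the starting amount of the target at the test stage.

    Returns (plate, truth): plate columns ``gene, well, cycle, fluorescence``;
    truth columns ``E, ratio`` indexed by gene (including the reference).
    """
    E = np.broadcast_to(np.asarray(true_E, dtype=float), (n_genes,)).copy()
    ratio = np.broadcast_to(np.asarray(true_ratio, dtype=float), (n_genes,)).copy()
    if np.any((E <= 1.0) | (E > 2.0)):
        raise ConfigError("amplification efficiencies must lie in (1, 2]")
    if np.any(ratio <= 0):
        raise ConfigError("true ratios must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cycles = np.arange(1, n_cycles + 1)
    rows = []

    def curve(E_g: float, start: float) -> np.ndarray:
        f = np.minimum(start * E_g ** cycles, plateau)
        if noise_sd > 0:
            f = f * np.exp(rng.normal(0.0, noise_sd, size=f.shape))
        return f

    baseline, test = stages
    gene_ids = [f"T{i:03d}" for i in range(n_genes)] + [REFERENCE_GENE]
    truth = pd.DataFrame(
        {"E": np.append(E, 2.0), "ratio": np.append(ratio, 1.0)},
        index=pd.Index(gene_ids, name="gene"),
    )
    for gi, gene in enumerate(gene_ids):
        E_g = truth.at[gene, "E"]
        for stage in stages:
            amount = f0
            if gene != REFERENCE_GENE and stage == test:
                amount = f0 * truth.at[gene, "ratio"]
            for rep in range(1, n_replicates + 1):
                f = curve(E_g, amount)
                well = f"{gene}_{stage}_{rep}"
                rows.extend(
                    {"gene": gene, "well": well, "cycle": int(c), "fluorescence": float(v)}
                    for c, v in zip(cycles, f)
                )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Temperature series
# ---------------------------------------------------------------------------


def simulate_temperature_series(
    duration_h: float,
    interval_min: int = 15,
    profile=25.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    start: str = "2011-07-30T00:00:00",
) -> pd.DataFrame:
    """Evenly spaced timestamped skin-temperature readings.

    ``profile`` is either a constant (degrees C) or a callable mapping elapsed
    hours to degrees C.  ``noise_sd`` adds Gaussian measurement noise (default
    none, so constant profiles ignore the seed).
    """
    total_min = duration_h * 60.0
    n = total_min / interval_min
    if duration_h <= 0 or abs(n - round(n)) > 1e-9:
        raise ConfigError("interval must evenly divide a positive duration")
    n = int(round(n))
    hours = np.arange(1, n + 1) * interval_min / 60.0
    temps = np.array([profile(h) for h in hours]) if callable(profile) else np.full(n, float(profile))
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        temps = temps + rng.normal(0.0, noise_sd, size=n)
    timestamps = pd.date_range(
        start=pd.Timestamp(start) + pd.Timedelta(minutes=interval_min),
        periods=n, freq=f"{interval_min}min",
    )
    return pd.DataFrame({"timestamp": timestamps, "temperature_C": temps})


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_outputs(outdir, matrix: ExpressionMatrix, controls: NegativeControls,
                  truth: pd.DataFrame) -> None:
    """Write the simulator outputs as TSV into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.write_tsv(outdir / "expression.tsv")
    controls.write_tsv(outdir / "negative_controls.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
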