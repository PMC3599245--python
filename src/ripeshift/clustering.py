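"""Pearson-distance k-means on stage profiles and the cluster-shift taxonomy.

Each (gene, condition) pair contributes one profile: the mean log2 intensity
at the ordered stages (BV, EV, H).  Profiles from all conditions are pooled,
standardized, and clustered once with k-means under the correlation distance
d(x, y) = 1 - r(x, y), so cluster identities are directly comparable across
conditions.  Every cluster receives a template label — the direction of
change at each later stage relative to BV and the onset stage — and a gene's
"cluster shift" between the control and a treatment is read off the labels:

* no-effect         same template in treatment and control
* delayed           same direction class, onset one stage later
* anticipated       same direction class, onset earlier
* novel-modulation  modulated in the treatment but not the control
* non-modulation    modulated in the control but not the treatment
* other             direction class changes (e.g. down -> up)

The per-gene effect group (common / different / PB-specific / V-specific /
none) summarizes the two per-treatment shift classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

NO_EFFECT = "no-effect"
DELAYED = "delayed"
ANTICIPATED = "anticipated"
NOVEL = "novel-modulation"
NON_MODULATION = "non-modulation"
OTHER = "other"

GROUP_COMMON = "common"
GROUP_DIFFERENT = "different"
GROUP_PB = "PB-specific"
GROUP_V = "V-specific"
GROUP_NONE = "none"


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


def stage_profiles(
    matrix: ExpressionMatrix,
    condition: str,
    genes=None,
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mean log2 profile over the ordered stages of one condition."""
    sub = matrix if genes is None else matrix.subset_genes(genes)
    stages = list(stages) if stages is not None else [
        s for s in sub.stages
        if ((sub.meta["treatment"] == condition) & (sub.meta["stage"] == s)).any()
    ]
    cols = {}
    for stage in stages:
        try:
            grp = sub.group_values(condition, stage)
        except KeyError as exc:
            raise KeyError(f"condition {condition!r} lacks stage {stage!r}") from exc
        cols[stage] = np.log2(grp.to_numpy(float)).mean(axis=1)
    return pd.DataFrame(cols, index=sub.genes)


def pooled_profiles(
    matrix: ExpressionMatrix,
    gene_sets: dict[str, set],
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Stack per-condition profiles, indexed by (gene, condition)."""
    frames = []
    for condition, genes in gene_sets.items():
        prof = stage_profiles(matrix, condition, sorted(genes), stages)
        prof.index = pd.MultiIndex.from_product(
            [prof.index, [condition]], names=["gene", "condition"]
        )
        frames.append(prof)
    return pd.concat(frames)


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2], 0 for positive affine copies."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("Pearson distance undefined for constant profiles")
    return float(1.0 - np.dot(x, y) / (nx * ny))


def _standardize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise center and scale to unit norm; returns (z, usable mask)."""
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    usable = norms > 1e-12
    z = np.zeros_like(centered)
    z[usable] = centered[usable] / norms[usable, None]
    return z, usable


# ---------------------------------------------------------------------------
# k-means under correlation distance
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    centroids: np.ndarray          # k x n_stages, standardized space
    assignments: pd.Series         # cluster id per (gene, condition)
    objective: float               # total within-cluster Pearson distance
    stages: list[str]
    fc_centroids: np.ndarray       # k x n_stages mean log2 profile rel. to baseline


def _corr_to_centroids(z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    c = centroids - centroids.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    norms[norms == 0] = 1.0
    return z @ (c / norms[:, None]).T


def _lloyd(z: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    for _ in range(max_iter):
        corr = _corr_to_centroids(z, centers)
        labels = np.argmax(corr, axis=1)
        new_centers = np.empty_like(centers)
        for j in range(k):
            members = z[labels == j]
            if members.size == 0:
                # reseed an empty cluster to the worst-fit profile
                worst = np.argmin(corr.max(axis=1))
                new_centers[j] = z[worst]
            else:
                new_centers[j] = members.mean(axis=0)
        if np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    corr = _corr_to_centroids(z, centers)
    labels = np.argmax(corr, axis=1)
    objective = float(np.sum(1.0 - corr[np.arange(len(labels)), labels]))
    return labels, centers, objective


def _farthest_point_init(z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    first = int(rng.integers(len(z)))
    chosen = [first]
    min_corr = _corr_to_centroids(z, z[[first]])[:, 0]
    for _ in range(1, k):
        nxt = int(np.argmin(min_corr))
        chosen.append(nxt)
        corr = _corr_to_centroids(z, z[[nxt]])[:, 0]
        min_corr = np.maximum(min_corr, corr)
    return z[chosen].copy()


def kmeans_pearson(
    profiles: pd.DataFrame,
    k: int = 8,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterModel:
    """k-means with d = 1 - Pearson correlation on pooled stage profiles.

    Profiles are standardized (zero mean, unit norm) so correlation distance
    is a monotone function of Euclidean distance; centroids are means of
    standardized member profiles.  Initialization is greedy farthest-point
    seeding; the best of ``n_init`` restarts by total within-cluster distance
    is kept.  Constant profiles are excluded with a warning.
    """
    arr = profiles.to_numpy(float)
    z, usable = _standardize(arr)
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} constant profile(s) excluded from clustering",
            RuntimeWarning,
        )
    zu = z[usable]
    if len(zu) < k:
        raise ValueError(f"need >= {k} usable non-constant profiles, got {len(zu)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1]))
    best = None
    for _ in range(n_init):
        centers0 = _farthest_point_init(zu, k, rng)
        labels, centers, obj = _lloyd(zu, centers0, max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (labels, centers, obj)
    labels, centers, obj = best

    assignments = pd.Series(np.full(len(profiles), -1, dtype=np.int64), index=profiles.index)
    assignments.iloc[np.flatnonzero(usable)] = labels
    stages = list(profiles.columns)
    rel = arr - arr[:, [0]]  # log2 profile relative to the baseline stage
    fc_centroids = np.zeros((k, arr.shape[1]))
    ui = np.flatnonzero(usable)
    for j in range(k):
        members = rel[ui[labels == j]]
        if len(members):
            fc_centroids[j] = members.mean(axis=0)
    return ClusterModel(
        centroids=centers, assignments=assignments, objective=obj,
        stages=stages, fc_centroids=fc_centroids,
    )


def brute_force_best_partition(profiles: pd.DataFrame, k: int = 2) -> tuple[float, tuple]:
    """Exhaustive-optimum k-partition by total within-cluster Pearson distance.

    Only feasible for tiny inputs; intended as an independent oracle.
    """
    arr = profiles.to_numpy(float)
    z, usable = _standardize(arr)
    if not usable.all():
        raise ValueError("constant profiles in oracle input")
    n = len(z)
    best_obj, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        lab = np.asarray(labels)
        obj = 0.0
        for j in range(k):
            members = z[lab == j]
            centroid = members.mean(axis=0)
            c = centroid - centroid.mean()
            norm = np.linalg.norm(c)
            if norm == 0:
                obj += len(members)  # correlation 0 contribution, d = 1 each
                continue
            obj += float(np.sum(1.0 - members @ (c / norm)))
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, tuple(lab)
    return best_obj, best_labels


# ---------------------------------------------------------------------------
# Template labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateLabel:
    """Direction of each later stage vs baseline, plus class and onset."""

    directions: tuple[str, ...]   # one of down/flat/up per non-baseline stage
    cls: str                      # 'down', 'up', 'flat' or 'other' (mixed)
    onset: str | None             # stage name of first non-flat direction

    @property
    def modulated(self) -> bool:
        return self.cls in ("down", "up")


def template_from_log2_profile(
    profile: np.ndarray, stages: list[str], fc_threshold: float = 2.0
) -> TemplateLabel:
    """Threshold a log2 profile (relative or absolute) into a template label."""
    profile = np.asarray(profile, float)
    log_thr = np.log2(fc_threshold)
    rel = profile[1:] - profile[0]
    dirs = tuple(np.select([rel <= -log_thr, rel >= log_thr], ["down", "up"], "flat"))
    has_down, has_up = "down" in dirs, "up" in dirs
    if has_down and has_up:
        cls = OTHER
    elif has_down:
        cls = "down"
    elif has_up:
        cls = "up"
    else:
        cls = "flat"
    onset = None
    for stage, d in zip(stages[1:], dirs):
        if d != "flat":
            onset = stage
            break
    return TemplateLabel(directions=dirs, cls=cls, onset=onset)


def assign_templates(model: ClusterModel, fc_threshold: float = 2.0) -> list[TemplateLabel]:
    """Template label per cluster from its mean log2 fold-change centroid."""
    labels = [
        template_from_log2_profile(model.fc_centroids[j], model.stages, fc_threshold)
        for j in range(model.fc_centroids.shape[0])
    ]
    if any(lab.cls == OTHER for lab in labels):
        warnings.warn("mixed up/down centroid(s) labeled 'other'", RuntimeWarning)
    return labels


# ---------------------------------------------------------------------------
# Shift taxonomy
# ---------------------------------------------------------------------------


@dataclass
class ShiftRecord:
    gene: str
    label_C: TemplateLabel | None
    label_PB: TemplateLabel | None
    label_V: TemplateLabel | None
    shift_PB: str
    shift_V: str
    effect_group: str


def select_shift_candidates(
    modulated_sets: dict[str, set],
    profiles_fc: pd.DataFrame,
    fc_min: float = 3.0,
    exclude: set | None = None,
) -> set:
    """Genes eligible for shift analysis.

    Modulated in >= 1 condition, with max |log2 FC| over later stages >=
    log2(fc_min) in >= 1 condition, minus genes already found by the direct
    stage-wise comparison.  ``profiles_fc`` is indexed by (gene, condition)
    with one column per stage of mean log2 intensity.
    """
    exclude = exclude or set()
    union = set().union(*modulated_sets.values()) if modulated_sets else set()
    log_thr = np.log2(fc_min)
    arr = profiles_fc.to_numpy(float)
    rel_max = np.abs(arr[:, 1:] - arr[:, [0]]).max(axis=1)
    passing = set(
        profiles_fc.index.get_level_values("gene")[rel_max >= log_thr]
    )
    return (union & passing) - exclude


def _shift_for_treatment(
    label_c: TemplateLabel | None, label_t: TemplateLabel | None,
    mod_c: bool, mod_t: bool, stages: list[str],
) -> str:
    if mod_c and not mod_t:
        return NON_MODULATION
    if mod_t and not mod_c:
        return NOVEL
    if not mod_c and not mod_t:
        return NO_EFFECT
    if label_c is None or label_t is None:
        raise ValueError("modulated gene without a template label")
    if label_t == label_c:
        return NO_EFFECT
    if label_t.cls != label_c.cls:
        return OTHER
    order = {s: i for i, s in enumerate(stages)}
    onset_c, onset_t = order.get(label_c.onset), order.get(label_t.onset)
    if onset_c is None or onset_t is None:
        return OTHER
    if onset_t > onset_c:
        return DELAYED
    if onset_t < onset_c:
        return ANTICIPATED
    return OTHER  # same class and onset but different late behaviour


def classify_shift(
    gene: str,
    label_C: TemplateLabel | None,
    label_PB: TemplateLabel | None,
    label_V: TemplateLabel | None,
    modulated: dict[str, bool],
    stages: list[str] = ("BV", "EV", "H"),
) -> ShiftRecord:
    """Per-gene shift classes for PB and V and the derived effect group.

    A pure function of template labels and modulation flags.  A label must be
    present whenever the corresponding modulation flag is set.
    """
    stages = list(stages)
    for cond, lab in (("C", label_C), ("PB", label_PB), ("V", label_V)):
        if modulated.get(cond, False) and lab is None:
            raise ValueError(f"gene {gene!r}: modulated in {cond} but no label")
    shift_pb = _shift_for_treatment(label_C, label_PB, modulated.get("C", False),
                                    modulated.get("PB", False), stages)
    shift_v = _shift_for_treatment(label_C, label_V, modulated.get("C", False),
                                   modulated.get("V", False), stages)
    shifted_pb = shift_pb != NO_EFFECT
    shifted_v = shift_v != NO_EFFECT
    if shifted_pb and shifted_v:
        group = GROUP_COMMON if shift_pb == shift_v else GROUP_DIFFERENT
    elif shifted_pb:
        group = GROUP_PB
    elif shifted_v:
        group = GROUP_V
    else:
        group = GROUP_NONE
    return ShiftRecord(gene, label_C, label_PB, label_V, shift_pb, shift_v, group)


def shift_table(records: list[ShiftRecord]) -> pd.DataFrame:
    """Flatten shift records into the shifts TSV layout."""

    def fmt(lab: TemplateLabel | None) -> str:
        if lab is None:
            return "not-modulated"
        if not lab.modulated:
            return "flat" if lab.cls == "flat" else "other"
        return f"{lab.cls}@{lab.onset}"

    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "label_C": [fmt(r.label_C) for r in records],
            "label_PB": [fmt(r.label_PB) for r in records],
            "label_V": [fmt(r.label_V) for r in records],
            "shift_PB": [r.shift_PB for r in records],
            "shift_V": [r.shift_V for r in records],
            "effect_group": [r.effect_group for r in records],
        }
    ).set_index("gene")
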