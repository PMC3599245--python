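"""Expression-matrix data model and basic operations.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
normalized linear fluorescence intensities together with per-sample metadata
(treatment, developmental stage, biological replicate).  Sample IDs encode the
metadata as ``treatment_stage_replicate`` (e.g. ``PB_EV_2``).

Detection calling follows the negative-control convention of two-color/array
platforms: a gene counts as expressed in a (treatment, stage) group when its
intensity exceeds the per-chip mean of the negative-control probes in at least
``min_replicates`` of that group's replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


def parse_sample_id(sample_id: str) -> tuple[str, str, int]:
    """Split ``treatment_stage_replicate`` into its components."""
    parts = sample_id.split("_")
    if len(parts) != 3:
        raise FormatError(
            f"sample ID {sample_id!r} is not of the form treatment_stage_replicate"
        )
    treatment, stage, rep = parts
    try:
        replicate = int(rep)
    except ValueError as exc:
        raise FormatError(f"sample ID {sample_id!r}: replicate {rep!r} is not an integer") from exc
    return treatment, stage, replicate


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of positive linear intensities with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    meta
        DataFrame indexed by sample ID with columns ``treatment``, ``stage``,
        ``replicate``.  If omitted, metadata is parsed from the sample IDs.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            records = [parse_sample_id(s) for s in self.values.columns]
            self.meta = pd.DataFrame(
                records, columns=["treatment", "stage", "replicate"],
                index=self.values.columns,
            )
        self.validate()

    def validate(self) -> None:
        dup_genes = self.values.index[self.values.index.duplicated()]
        if len(dup_genes):
            raise FormatError(f"duplicated gene ID(s): {sorted(set(dup_genes))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()]
        if len(dup_samples):
            raise FormatError(f"duplicated sample ID(s): {sorted(set(dup_samples))}")
        if not set(self.values.columns) <= set(self.meta.index):
            missing = set(self.values.columns) - set(self.meta.index)
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad = self.values.index[(~np.isfinite(arr) | (arr <= 0)).any(axis=1)]
            raise FormatError(f"non-positive or non-finite intensity in gene(s): {list(bad[:5])}")
        sizes = self.meta.loc[self.values.columns].groupby(["treatment", "stage"]).size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise FormatError(f"(treatment, stage) group(s) with < 2 replicates: {small}")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.meta.loc[self.samples, "treatment"]))

    @property
    def stages(self) -> list[str]:
        return list(pd.unique(self.meta.loc[self.samples, "stage"]))

    def group_samples(self, treatment: str, stage: str) -> list[str]:
        m = self.meta.loc[self.samples]
        sel = (m["treatment"] == treatment) & (m["stage"] == stage)
        ids = list(m.index[sel])
        if not ids:
            raise KeyError(f"no samples for group ({treatment}, {stage})")
        return ids

    def group_values(self, treatment: str, stage: str) -> pd.DataFrame:
        return self.values[self.group_samples(treatment, stage)]

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.meta)

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class NegativeControls:
    """Per-sample negative-control probe fluorescences."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for sample, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 1:
                raise FormatError(f"sample {sample!r} has no negative-control values")
            if np.any(arr <= 0):
                raise FormatError(f"sample {sample!r} has non-positive control values")
            self.values[sample] = arr

    @property
    def means(self) -> pd.Series:
        """Per-chip arithmetic mean of the negative-control fluorescence."""
        return pd.Series({s: float(np.mean(v)) for s, v in self.values.items()})

    def write_tsv(self, path) -> None:
        rows = [(s, x) for s, arr in self.values.items() for x in arr]
        pd.DataFrame(rows, columns=["sample", "value"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "NegativeControls":
        df = pd.read_csv(path, sep="\t")
        return cls({s: g["value"].to_numpy(float) for s, g in df.groupby("sample", sort=False)})


def call_expressed(
    matrix: ExpressionMatrix,
    controls: NegativeControls,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Detection call against the per-chip negative-control mean.

    Returns
    -------
    expressed : DataFrame
        Boolean, genes x (treatment, stage) MultiIndex columns; True when the
        gene's intensity strictly exceeds its own chip's control mean in at
        least ``min_replicates`` replicates of the group.
    retained : Series
        Boolean per gene: expressed in at least one group.
    """
    means = controls.means
    missing = set(matrix.samples) - set(means.index)
    if missing:
        raise FormatError(f"samples without negative controls: {sorted(missing)}")
    groups = (
        matrix.meta.loc[matrix.samples]
        .groupby(["treatment", "stage"], sort=False)
        .groups
    )
    cols = {}
    for (treatment, stage), sample_ids in groups.items():
        sample_ids = list(sample_ids)
        if min_replicates > len(sample_ids):
            raise ValueError(
                f"min_replicates={min_replicates} exceeds group size "
                f"{len(sample_ids)} for ({treatment}, {stage})"
            )
        above = matrix.values[sample_ids].gt(means[sample_ids], axis=1)
        cols[(treatment, stage)] = above.sum(axis=1) >= min_replicates
    expressed = pd.DataFrame(cols)
    expressed.columns = pd.MultiIndex.from_tuples(expressed.columns, names=["treatment", "stage"])
    retained = expressed.any(axis=1)
    retained.name = "retained"
    return expressed, retained


def signed_ratio(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Signed linear fold change: B/A when B >= A, else -(A/B).

    Magnitude is always >= 1; sign is positive iff mean(B) >= mean(A).  The
    convention matches tables that mix entries like +12.22 and -11.70.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    up = mean_b >= mean_a
    return np.where(up, mean_b / mean_a, -mean_a / mean_b)


def fold_change(
    matrix: ExpressionMatrix,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene signed linear fold change between two (treatment, stage) groups.

    Group means are arithmetic means of the linear intensities over replicates.
    """
    ma = matrix.group_values(*group_a).mean(axis=1)
    mb = matrix.group_values(*group_b).mean(axis=1)
    fc = signed_ratio(ma.to_numpy(), mb.to_numpy())
    return pd.DataFrame(
        {"fc": fc, "direction": np.where(fc >= 0, "up", "down")},
        index=matrix.genes,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    variance_ratio: np.ndarray    # fraction of variance per retained component
    constant: bool = False        # matrix had zero variance after centering


def sample_pca(
    matrix: ExpressionMatrix,
    log_transform: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Sample-level PCA of the (log2) expression matrix.

    Samples are observations, genes are features; features are centered (the
    standard gene-centering for array sample PCA), no unit-variance scaling.
    Scores are reproducible up to component sign.
    """
    X = matrix.log2() if log_transform else matrix.values
    data = X.to_numpy(float).T  # samples x genes
    if data.shape[0] < 2:
        raise ValueError("sample PCA needs at least 2 samples")
    centered = data - data.mean(axis=0)
    if np.allclose(centered, 0):
        k = n_components or min(data.shape)
        scores = pd.DataFrame(
            np.zeros((data.shape[0], k)), index=matrix.samples,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return PCAResult(scores, np.zeros(k), constant=True)
    k = n_components or min(data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    transformed = pca.fit_transform(data)
    scores = pd.DataFrame(
        transformed, index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(transformed.shape[1])],
    )
    return PCAResult(scores, pca.explained_variance_ratio_, constant=False)
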