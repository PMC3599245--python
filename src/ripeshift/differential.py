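"""Venn partitioning of pairwise DE results and ripening-trend labeling.

A gene that looks induced in a defoliated treatment at the end of veraison may
simply have failed to follow the control's BV->EV downregulation — it is "not
downregulated" (NDR) rather than genuinely induced; symmetrically, "not
upregulated" (NUR).  Labeling crosses the DE direction in the treatment-vs-
control contrast with the control's own BV->EV trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, fold_change

NDR = "NDR"
NUR = "NUR"
GENUINELY_UP = "genuinely-up"
GENUINELY_DOWN = "genuinely-down"


@dataclass
class VennPartition:
    """Disjoint common / PB-only / V-only split of two DE gene sets."""

    common: frozenset
    pb_only: frozenset
    v_only: frozenset
    directions_pb: pd.Series
    directions_v: pd.Series
    stage: str | None = None

    def __post_init__(self) -> None:
        assert not self.common & self.pb_only
        assert not self.common & self.v_only
        assert not self.pb_only & self.v_only

    @property
    def total_pb(self) -> int:
        """Size of the full PB-vs-C DE set: |common| + |PB-only|."""
        return len(self.common) + len(self.pb_only)

    @property
    def total_v(self) -> int:
        return len(self.common) + len(self.v_only)

    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "pb_only": len(self.pb_only),
            "v_only": len(self.v_only),
            "total_pb": self.total_pb,
            "total_v": self.total_v,
        }


def _called_genes(de: pd.DataFrame) -> pd.Index:
    if "called" in de.columns:
        return de.index[de["called"].astype(bool)]
    return de.index


def venn_partition(de_pb: pd.DataFrame, de_v: pd.DataFrame) -> VennPartition:
    """Partition two DETables (same stage) into common / PB-only / V-only."""
    stage_pb = de_pb.attrs.get("stage")
    stage_v = de_v.attrs.get("stage")
    if stage_pb is not None and stage_v is not None and stage_pb != stage_v:
        raise ValueError(f"DE tables from different stages: {stage_pb!r} vs {stage_v!r}")
    set_pb = set(_called_genes(de_pb))
    set_v = set(_called_genes(de_v))
    common = frozenset(set_pb & set_v)
    return VennPartition(
        common=common,
        pb_only=frozenset(set_pb - set_v),
        v_only=frozenset(set_v - set_pb),
        directions_pb=de_pb.loc[sorted(set_pb), "direction"] if "direction" in de_pb else pd.Series(dtype=object),
        directions_v=de_v.loc[sorted(set_v), "direction"] if "direction" in de_v else pd.Series(dtype=object),
        stage=stage_pb or stage_v,
    )


def control_trend(
    matrix: ExpressionMatrix,
    genes=None,
    treatment: str = "C",
    stage_from: str = "BV",
    stage_to: str = "EV",
    fc_threshold: float = 2.0,
) -> pd.Series:
    """Control-ripening trend per gene: 'down', 'up' or 'flat'.

    down iff signed FC(stage_to / stage_from in the control) <= -fc_threshold,
    up iff >= +fc_threshold, flat otherwise.
    """
    sub = matrix if genes is None else matrix.subset_genes(genes)
    fc = fold_change(sub, (treatment, stage_from), (treatment, stage_to))["fc"]
    trend = pd.Series(
        np.select([fc <= -fc_threshold, fc >= fc_threshold], ["down", "up"], "flat"),
        index=fc.index, name="trend",
    )
    return trend


def classify_ndr_nur(genes, trends: pd.Series, directions: pd.Series) -> pd.Series:
    """NDR/NUR vs genuine modulation labels for a DE gene set.

    DE-up with control trend down -> NDR; DE-down with control trend up ->
    NUR; otherwise genuinely-up / genuinely-down.  Total and single-valued.
    """
    labels = {}
    for gene in genes:
        if gene not in trends.index or pd.isna(trends.get(gene)):
            raise KeyError(f"gene {gene!r} has no control trend")
        if gene not in directions.index or pd.isna(directions.get(gene)):
            raise KeyError(f"gene {gene!r} has no DE direction")
        trend, direction = trends[gene], directions[gene]
        if direction == "up":
            labels[gene] = NDR if trend == "down" else GENUINELY_UP
        else:
            labels[gene] = NUR if trend == "up" else GENUINELY_DOWN
    return pd.Series(labels, name="classification", dtype=object)


NO_HIT = "no hit"


def summarize_categories(
    gene_set,
    annotation: pd.DataFrame,
    directions: pd.Series | None = None,
) -> pd.DataFrame:
    """Functional-category composition of a gene set.

    ``annotation`` maps gene -> ``category`` (index gene or a ``gene``
    column).  Unannotated genes fall into "no hit".  Returns per category the
    count, percentage of the set, and up/down tallies when ``directions`` is
    given; ``attrs['coverage']`` holds the annotated fraction.
    """
    genes = list(gene_set)
    if "gene" in annotation.columns:
        annotation = annotation.set_index("gene")
    cat = annotation["category"].reindex(genes)
    cat = cat.where(cat.notna() & (cat != ""), NO_HIT)
    counts = cat.value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100.0 * out["count"] / max(len(genes), 1)
    if directions is not None:
        d = directions.reindex(genes)
        out["n_up"] = cat[d == "up"].value_counts().reindex(out.index, fill_value=0)
        out["n_down"] = cat[d == "down"].value_counts().reindex(out.index, fill_value=0)
    out.index.name = "category"
    out.attrs["coverage"] = float((cat != NO_HIT).mean()) if genes else 0.0
    return out
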