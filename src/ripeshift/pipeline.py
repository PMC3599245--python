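"""End-to-end orchestration of the defoliation time-course analysis.

Stages: simulate (or load) -> detection call -> pairwise SAM per stage ->
Venn partition with NDR/NUR labels at the end of veraison -> multiclass SAM
per condition -> pooled Pearson k-means with the shift taxonomy -> optional
functional-category summaries -> machine-readable report.

A single global seed is fanned out to named substreams (simulation, SAM
permutations, k-means initialization) so module-level reruns reproduce the
pipeline run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, differential
from .expression import ExpressionMatrix, NegativeControls, call_expressed
from .sam import SAMConfig, sam_multiclass_modulated, sam_pairwise
from .simulate import SimConfig, simulate_experiment

log = logging.getLogger("ripeshift")

# stable offsets for deriving substream seeds from the global seed
_SUBSTREAMS = {"simulation": 11, "sam": 23, "kmeans": 37}


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-component seed derived from the global seed."""
    return (seed * 1_000_003 + _SUBSTREAMS[name]) % (2 ** 31 - 1)


@dataclass
class RunConfig:
    seed: int = 7
    sim: SimConfig | None = field(default_factory=SimConfig)
    matrix_path: str | None = None
    controls_path: str | None = None
    annotation_path: str | None = None
    control: str = "C"
    treatments: tuple[str, str] = ("PB", "V")
    stages: tuple[str, ...] = ("BV", "EV", "H")
    venn_stage: str = "EV"
    fc_threshold: float = 2.0
    fc_min_shift: float = 3.0
    trend_fc_threshold: float = 2.0
    k: int = 8
    n_init: int = 10
    sam: SAMConfig = field(default_factory=SAMConfig)
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim")) if isinstance(raw.get("sim"), dict) else None
        sam = SAMConfig(**raw.pop("sam")) if isinstance(raw.get("sam"), dict) else SAMConfig()
        cfg = cls(sim=sim, sam=sam, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        return cfg

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "sim": asdict(self.sim) if self.sim else None,
            "sam": asdict(self.sam),
            "fc_threshold": self.fc_threshold,
            "fc_min_shift": self.fc_min_shift,
            "k": self.k,
            "n_init": self.n_init,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def _load_inputs(config: RunConfig):
    if config.matrix_path:
        matrix = ExpressionMatrix.read_tsv(config.matrix_path)
        controls = NegativeControls.read_tsv(config.controls_path)
        truth = None
    else:
        sim = replace(config.sim, seed=substream_seed(config.seed, "simulation"))
        matrix, controls, truth = simulate_experiment(sim)
    return matrix, controls, truth


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict and writes tables.

    The report's Venn sum identities are asserted before returning, and every
    reported count is re-derivable from the emitted tables.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, df: pd.DataFrame) -> None:
        if outdir is not None:
            df.to_csv(outdir / name, sep="\t")

    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    matrix, controls, truth = _load_inputs(config)
    log.info("input: %d genes x %d samples", len(matrix.genes), len(matrix.samples))
    if truth is not None:
        emit("truth.tsv", truth)

    # 1. detection call
    expressed, retained = call_expressed(matrix, controls)
    retained_genes = list(retained.index[retained])
    report["n_retained"] = len(retained_genes)
    log.info("detection call: %d of %d genes retained", len(retained_genes), len(matrix.genes))
    if not retained_genes:
        raise PipelineError("call_expressed", "no gene retained")

    sam_cfg = replace(config.sam, seed=substream_seed(config.seed, "sam"))

    # 2. pairwise SAM per stage and treatment
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    report["pairwise_de_counts"] = {}
    for treatment in config.treatments:
        for stage in config.stages:
            try:
                de = sam_pairwise(
                    matrix, (config.control, treatment, stage),
                    fc_threshold=config.fc_threshold, config=sam_cfg,
                    genes=retained_genes,
                )
            except KeyError as exc:
                raise PipelineError("sam_pairwise", str(exc)) from exc
            de_tables[(treatment, stage)] = de
            n = int(de["called"].sum())
            report["pairwise_de_counts"][f"{treatment}_vs_{config.control}_{stage}"] = n
            emit(f"de_{treatment}_vs_{config.control}_{stage}.tsv", de)
            log.info("pairwise SAM %s vs %s at %s: %d DE genes",
                     treatment, config.control, stage, n)

    # 3. Venn partition + NDR/NUR at the focal stage
    t_pb, t_v = config.treatments
    partition = differential.venn_partition(
        de_tables[(t_pb, config.venn_stage)], de_tables[(t_v, config.venn_stage)]
    )
    counts = partition.counts()
    assert counts["common"] + counts["pb_only"] == counts["total_pb"]
    assert counts["common"] + counts["v_only"] == counts["total_v"]
    report["venn"] = counts

    de_union = sorted(partition.common | partition.pb_only | partition.v_only)
    trend_labels = pd.DataFrame(index=pd.Index(de_union, name="gene"))
    if de_union:
        trends = differential.control_trend(
            matrix, de_union, treatment=config.control,
            fc_threshold=config.trend_fc_threshold,
        )
        for treatment, de in ((t_pb, de_tables[(t_pb, config.venn_stage)]),
                              (t_v, de_tables[(t_v, config.venn_stage)])):
            genes = sorted(set(de_union) & set(differential._called_genes(de)))
            labels = differential.classify_ndr_nur(genes, trends, de["direction"])
            trend_labels[f"classification_{treatment}"] = labels.reindex(de_union)
        trend_labels["trend_C"] = trends
    emit("venn_trend_labels.tsv", trend_labels)
    report["ndr_nur"] = {
        col: trend_labels[col].value_counts().to_dict()
        for col in trend_labels.columns if col.startswith("classification")
    }

    # 4. multiclass SAM per condition
    conditions = (config.control, *config.treatments)
    modulated_sets: dict[str, set] = {}
    multi_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        table = sam_multiclass_modulated(
            matrix, cond, stages=list(config.stages),
            fc_threshold=config.fc_threshold, config=sam_cfg, genes=retained_genes,
        )
        multi_tables[cond] = table
        modulated_sets[cond] = set(table.index[table["modulated"]])
        emit(f"modulated_{cond}.tsv", table)
        log.info("multiclass SAM %s: %d modulated genes", cond, len(modulated_sets[cond]))
    report["modulated_counts"] = {c: len(s) for c, s in modulated_sets.items()}

    # 5. clustering + shift taxonomy on the union of modulated genes
    union = sorted(set().union(*modulated_sets.values()))
    report["shift"] = {"n_clustered_genes": len(union)}
    shift_df = pd.DataFrame()
    if len(union) >= config.k:
        profiles = clustering.pooled_profiles(
            matrix, {c: set(union) for c in conditions}, stages=list(config.stages)
        )
        model = clustering.kmeans_pearson(
            profiles, k=config.k, n_init=config.n_init,
            seed=substream_seed(config.seed, "kmeans"),
        )
        templates = clustering.assign_templates(model, fc_threshold=config.fc_threshold)
        records = []
        for gene in union:
            labels = {}
            for cond in conditions:
                cid = int(model.assignments.get((gene, cond), -1))
                labels[cond] = templates[cid] if cid >= 0 else None
            records.append(clustering.classify_shift(
                gene, labels[config.control], labels[t_pb], labels[t_v],
                {c: gene in modulated_sets[c] for c in conditions},
                stages=list(config.stages),
            ))
        shift_df = clustering.shift_table(records)
        direct = set().union(*(set(differential._called_genes(de)) for de in de_tables.values()))
        candidates = clustering.select_shift_candidates(
            modulated_sets, profiles, fc_min=config.fc_min_shift, exclude=direct,
        )
        shift_df["candidate"] = shift_df.index.isin(candidates)
        emit("shifts.tsv", shift_df)
        report["shift"].update({
            "n_candidates": len(candidates),
            "shift_PB": shift_df["shift_PB"].value_counts().to_dict(),
            "shift_V": shift_df["shift_V"].value_counts().to_dict(),
            "effect_group": shift_df["effect_group"].value_counts().to_dict(),
        })
        log.info("shift taxonomy: %d genes clustered, %d candidates",
                 len(union), len(candidates))

    # 6. category summaries
    if config.annotation_path:
        annotation = pd.read_csv(config.annotation_path, sep="\t")
        summary = differential.summarize_categories(de_union, annotation)
        emit("category_summary.tsv", summary)
        report["categories"] = {
            "coverage": summary.attrs["coverage"],
            "counts": summary["count"].to_dict(),
        }

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        manifest = {"config_hash": report["config_hash"], "seed": config.seed,
                    "outputs": sorted(p.name for p in outdir.glob("*.tsv"))}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
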