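"""End-to-end pipeline driver: QC -> normalize -> hormone calling ->
multi-hormone exclusion -> stratified GCN -> per-node markers.

The run configuration is a flat JSON document; every field has a default,
and the fully expanded effective configuration is logged alongside the
outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as iio
from .gcn import GCNParams, stratified_gcn
from .hormones import (
    call_hormone_classes,
    compute_quantile_cutoffs,
    filter_monohormonal,
    preset_call_config,
)
from .markers import DEGThresholds, find_markers
from .preprocess import (
    SMARTSEQ3_EXCLUDED_GENES,
    FeatureSelectionParams,
    QCParams,
    normalize,
    qc_filter,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    counts_path: str = ""
    platform: str = "tenx"
    hormone_preset: str = "mouse_adult_10x"
    scale_factor: float | None = None  # default: 1e5 for tenx, 1e6 for smartseq3
    excluded_genes: tuple = ()          # default: hormone list for smartseq3
    qc: QCParams | None = None
    features: FeatureSelectionParams = field(default_factory=FeatureSelectionParams)
    gcn: GCNParams = field(default_factory=GCNParams)
    deg: DEGThresholds = field(default_factory=DEGThresholds)
    downsample_seed: int = 0
    outdir: str = "isletgcn_out"

    def resolved(self) -> "RunConfig":
        cfg = dataclasses.replace(self)
        if cfg.scale_factor is None:
            cfg.scale_factor = 1e6 if cfg.platform == "smartseq3" else 1e5
        if not cfg.excluded_genes and cfg.platform == "smartseq3":
            cfg.excluded_genes = SMARTSEQ3_EXCLUDED_GENES
        if cfg.qc is None:
            cfg.qc = QCParams(platform=cfg.platform)
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {}
        for key, sub in (("qc", QCParams), ("features", FeatureSelectionParams),
                         ("gcn", GCNParams), ("deg", DEGThresholds)):
            if key in raw:
                kwargs[key] = sub(**raw.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        cfg = cls(**kwargs)
        if cfg.counts_path and not Path(cfg.counts_path).exists():
            raise FileNotFoundError(f"counts_path does not exist: {cfg.counts_path}")
        return cfg

    def effective_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, tuple):
                return list(x)
            return x

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.outdir``.

    Returns a dict of in-memory results (normalized matrix, hormone calls,
    hierarchy root, marker table, written paths).
    """
    cfg = config.resolved()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("isletgcn")
    previous_level = root_logger.level
    root_logger.setLevel(logging.INFO)
    root_logger.addHandler(handler)
    try:
        import isletgcn

        root_logger.info("isletgcn version %s", getattr(isletgcn, "__version__", "?"))
        root_logger.info(
            "effective config: %s", json.dumps(cfg.effective_dict(), sort_keys=True)
        )
        results: dict = {}

        def stage(name, fn, *args, **kwargs):
            try:
                root_logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                root_logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc

        counts = stage("read_counts", iio.read_counts, cfg.counts_path)
        counts, qc_report = stage("qc_filter", qc_filter, counts, cfg.qc)
        qc_report.to_csv(out / "qc_removed.tsv", sep="\t", index=False)
        norm = stage("normalize", normalize, counts, cfg.scale_factor,
                     cfg.excluded_genes)
        hcfg = preset_call_config(cfg.hormone_preset)
        cutoffs = stage("quantile_cutoffs", compute_quantile_cutoffs, norm, hcfg)
        calls = stage("call_hormones", call_hormone_classes, norm, cutoffs, hcfg)
        calls_out = calls.drop(columns=["positive_hormones"])
        calls_out.to_csv(out / "hormone_calls.tsv", sep="\t", index=True)
        mono, audit = stage("filter_monohormonal", filter_monohormonal, norm, calls)
        audit.to_csv(out / "hormone_class_audit.tsv", sep="\t", index=False)
        hierarchy = stage("stratified_gcn", stratified_gcn, mono,
                          cfg.features, cfg.gcn)
        iio.write_json(hierarchy.to_dict(), out / "hierarchy.json")
        labels_rows = []
        for node in _walk(hierarchy):
            if node.labels is not None:
                for cell, lab in node.labels.items():
                    labels_rows.append((node.name, cell, lab))
        labels_df = pd.DataFrame(labels_rows, columns=["node", "cell_id", "cluster"])
        labels_df.sort_values(["node", "cell_id"], kind="stable").to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        markers_df = pd.DataFrame()
        if hierarchy.labels is not None:
            markers_df = stage("find_markers", find_markers, mono,
                               hierarchy.labels, cfg.deg)
        markers_df.to_csv(out / "markers_root.tsv", sep="\t", index=False)
        results.update(
            counts=counts, norm=norm, calls=calls, audit=audit,
            hierarchy=hierarchy, markers=markers_df, outdir=out,
        )
        root_logger.info("pipeline complete: %s", out)
        return results
    finally:
        root_logger.removeHandler(handler)
        root_logger.setLevel(previous_level)
        handler.close()


def _walk(node):
    yield node
    for ch in node.children:
        yield from _walk(ch)
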