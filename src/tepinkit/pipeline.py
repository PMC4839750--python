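"""End-to-end pipeline: activity -> temporal network -> weighting ->
complex mining -> evaluation (-> enrichment), with a machine-readable
JSON-lines summary of every stage.

Weighted and unweighted runs share this single code path with weighting
toggled, so comparisons between the two differ only in the weighting stage
itself.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .activity import (
    DeviationDegreeDetector,
    GlobalThresholdDetector,
    active_sets,
    activity_histogram,
)
from .builder import build_tepin, network_properties
from .clustering import MarkovClustering, mine_temporal_complexes
from .datatypes import EvaluationReport, MCLParams
from .evaluation import annotate_complexes, evaluate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Threshold defaults follow the field conventions the evaluation adopts:
    overlap-score match threshold 0.2, redundancy-filter similarity 1.0 for
    MCL-style clusterers, enrichment significance 0.01.
    """

    pin_path: str = ""
    expression_path: str = ""
    complexes_path: str | None = None
    annotation_path: str | None = None
    out_dir: str = "tepinkit_out"
    detector: str = "deviation-degree"
    global_threshold: float = 0.0
    weighted: bool = True
    mcl: MCLParams = field(default_factory=MCLParams)
    os_threshold: float = 0.2
    similarity_threshold: float = 1.0
    alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        mcl = MCLParams(**raw.pop("mcl", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(mcl=mcl, **raw)

    def make_detector(self):
        if self.detector == "deviation-degree":
            return DeviationDegreeDetector()
        if self.detector == "global-threshold":
            return GlobalThresholdDetector(self.global_threshold)
        raise ValueError(f"unknown detector {self.detector!r}")


def _report_dict(report: EvaluationReport) -> dict:
    m = report.match
    return {
        "os_threshold": m.os_threshold,
        "n_predicted": m.n_predicted,
        "n_known": m.n_known,
        "TP": m.TP, "FP": m.FP, "MKC": m.MKC, "FN": m.FN,
        "perfect": m.perfect,
        "Sn": report.Sn, "Sp": report.Sp, "F": report.F,
        "average_predicted_size": report.average_predicted_size,
        "matched_known_percentage": report.matched_known_percentage,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``config.out_dir``, and
    return (and persist as summary.jsonl) the stage summaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: list[dict] = [{"stage": "config",
                            **dataclasses.asdict(config)}]

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    pin = stage("read_pin", lambda: io.read_ppi(config.pin_path))
    expr = stage("read_expression",
                 lambda: io.read_expression(config.expression_path))
    known = (stage("read_complexes",
                   lambda: io.read_complexes(config.complexes_path))
             if config.complexes_path else None)

    schedule = stage(
        "activity", lambda: active_sets(expr, config.make_detector())
    )
    hist = activity_histogram(schedule)
    summary.append({"stage": "activity", "n_genes": len(schedule.profiles),
                    "histogram": {str(k): v for k, v in hist.items()}})

    net = stage("build", lambda: build_tepin(pin, schedule))
    props = network_properties(net)
    summary.append({
        "stage": "build",
        "properties": props.to_dict(orient="records"),
    })
    io.write_tepin(net, out / "tepin")

    if config.weighted:
        from .weighting import weight_network

        net, elim = stage(
            "weight", lambda: weight_network(net, pin, expr, known)
        )
        summary.append({"stage": "weight",
                        "elimination_ratios": [float(r) for r in elim],
                        "mean_elimination_ratio": float(elim.mean())})
        io.write_tepin(net, out / "wtepin")

    mcl = MarkovClustering(**dataclasses.asdict(config.mcl))
    predicted = stage(
        "mine",
        lambda: mine_temporal_complexes(net, mcl, config.similarity_threshold),
    )
    io.write_complexes(predicted.catalog, out / "predicted_complexes.tsv")
    summary.append({"stage": "mine", "n_predicted": len(predicted)})

    report = None
    if known is not None:
        report = stage(
            "evaluate",
            lambda: evaluate(predicted.catalog, known, config.os_threshold),
        )
        summary.append({"stage": "evaluate", **_report_dict(report)})

    if config.annotation_path:
        ann = stage("read_annotation",
                    lambda: io.read_annotation(config.annotation_path))
        enrich = stage(
            "enrich",
            lambda: annotate_complexes(predicted.catalog, ann, config.alpha),
        )
        summary.append({
            "stage": "enrich",
            "bins": enrich["bins"],
            "n_significant": enrich["n_significant"],
            "significant_percentage": enrich["significant_percentage"],
        })

    with open(out / "summary.jsonl", "w", encoding="utf-8") as fh:
        for record in summary:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return {"summary": summary, "predicted": predicted, "report": report}
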