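"""End-to-end orchestration: simulate → preprocess → selectivity → differential → annotate.

Every stage writes its intermediate artifact as TSV under the output
directory, so each step can be inspected and re-tested in isolation; the run
ends with a plain-text summary report.  Stage outputs are pure functions of
(config, seed): the same config gives byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, preprocess, selectivity, synthetic
from .genomics import classify_catalog
from .preprocess import FilterParams
from .synthetic import SyntheticConfig, generate_annotation_tracks, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterParams = field(default_factory=FilterParams)
    level: str = "system"  # grouping level for selectivity
    design: str = "multi-class"  # or "two-class"
    adjust: str = "bh"  # or "none"
    p_threshold: float = 0.01
    q_threshold: float = 0.05
    top_k: int = 15
    seed: int | None = None  # overrides synthetic.seed when set

    def resolved(self) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if cfg.seed is not None:
            cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=int(cfg.seed))
        cfg.synthetic.validate()
        if cfg.design not in ("two-class", "multi-class"):
            raise ValueError(f"design must be 'two-class' or 'multi-class', got {cfg.design!r}")
        if cfg.adjust not in ("bh", "none"):
            raise ValueError(f"adjust must be 'bh' or 'none', got {cfg.adjust!r}")
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Read a plain-text key/value (YAML) pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = SyntheticConfig(**{
        k: (tuple(v) if isinstance(v, list) and k in ("expressed_group_frac", "class_probs")
            else [tuple(t) for t in v] if k == "planted_selective" else v)
        for k, v in raw.pop("synthetic", {}).items()
    })
    filt = FilterParams(**raw.pop("filter", {}))
    return PipelineConfig(synthetic=syn, filter=filt, **raw)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages, write artifacts + ``report.txt``, return the summary.

    On a stage failure the exception is re-raised annotated with the stage
    name; artifacts of completed stages remain on disk.
    """
    cfg = config.resolved()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "simulate"
    try:
        spots, annotation, catalog = generate_dataset(cfg.synthetic)
        write_dataset(spots, annotation, catalog, outdir)
        summary["probes_on_array"] = 2 * cfg.synthetic.n_ucrs
        summary["samples"] = annotation.shape[0]

        stage = "preprocess"
        pre = preprocess.preprocess_pipeline(spots, cfg.filter)
        pre.floored.values.to_csv(outdir / "expression_floored.tsv", sep="\t")
        pre.floored.detection.to_csv(outdir / "detection_mask.tsv", sep="\t")
        pre.report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        pre.log2.values.to_csv(outdir / "expression_normalized_log2.tsv", sep="\t")
        summary["floor_value"] = pre.floor_value
        summary["probes_retained"] = len(pre.retained)
        assert len(pre.retained) == int(pre.report["retained"].sum())

        stage = "selectivity"
        if pre.retained:
            sel = selectivity.selectivity_table(pre.normalized, annotation, cfg.level)
            sel.to_csv(outdir / "selectivity.tsv", sep="\t", index=False)
            top = sel.head(cfg.top_k)[["rank", "probe_id", "ic_bits", "top_group"]]
        else:
            sel = pd.DataFrame()
            top = pd.DataFrame(columns=["rank", "probe_id", "ic_bits", "top_group"])
        bidir = selectivity.call_bidirectional(pre.retained, catalog)
        pd.DataFrame({"ucr_id": bidir}).to_csv(outdir / "bidirectional.tsv", sep="\t", index=False)
        summary["ucr_bidirectional"] = len(bidir)
        summary["top_selectivity"] = top

        stage = "differential"
        adjust = cfg.adjust == "bh"
        if cfg.design == "two-class":
            labels = annotation.set_index("sample_id")["class"].reindex(pre.log2.sample_ids)
            tests = differential.two_class_t(pre.log2, labels.to_numpy(), adjust=adjust)
        else:
            labels = annotation.set_index("sample_id")["system_group"].reindex(pre.log2.sample_ids)
            tests = differential.multi_class_f(pre.log2, labels.to_numpy(), adjust=adjust)
        tests.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        summary["n_tests"] = len(tests)
        summary[f"n_p_lt_{cfg.p_threshold}"] = int((tests["p_value"] < cfg.p_threshold).sum())
        summary[f"n_q_lt_{cfg.q_threshold}"] = int((tests["q_value"] < cfg.q_threshold).sum())

        stage = "annotate"
        tracks = generate_annotation_tracks(catalog, cfg.synthetic.seed)
        context = classify_catalog(catalog, tracks)
        context.to_csv(outdir / "genomic_context.tsv", sep="\t", index=False)
        counts = context["genomic_class"].value_counts()
        for cls in ("exonic", "putative_exonic", "non_exonic"):
            summary[f"n_{cls}"] = int(counts.get(cls, 0))
    except Exception as exc:  # noqa: BLE001 — annotate with the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    lines = [
        "# T-UCR pipeline summary",
        f"seed: {cfg.synthetic.seed}",
        f"probes_on_array: {summary['probes_on_array']}",
        f"samples: {summary['samples']}",
        f"floor_value: {_fmt(summary['floor_value'])}",
        f"probes_retained: {summary['probes_retained']}",
        f"ucr_bidirectional: {summary['ucr_bidirectional']}",
        f"n_tests: {summary['n_tests']}",
        f"n_p_lt_{cfg.p_threshold}: {summary[f'n_p_lt_{cfg.p_threshold}']}",
        f"n_q_lt_{cfg.q_threshold}: {summary[f'n_q_lt_{cfg.q_threshold}']}",
        f"n_exonic: {summary['n_exonic']}",
        f"n_putative_exonic: {summary['n_putative_exonic']}",
        f"n_non_exonic: {summary['n_non_exonic']}",
        f"top_{cfg.top_k}_selectivity:",
    ]
    for row in summary["top_selectivity"].itertuples(index=False):
        lines.append(f"  {row.rank}\t{row.probe_id}\t{_fmt(row.ic_bits)}\t{row.top_group}")
    report_text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report_text)
    summary["report_path"] = outdir / "report.txt"
    summary["report_text"] = report_text
    return summary
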