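"""End-to-end orchestration: ingest/simulate -> detect -> normalize ->
differential expression -> signatures, with a machine-readable run summary.

One config drives both modes (real Cq exports or the synthetic generator);
all thresholds default to the profiling study's rules (detection window
15-30 cycles, expressed cut-off 28, FC >= 1.5, adjusted p <= 0.05).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from evmir.cq_io import (
    CqMatrix,
    SampleSheet,
    read_cq_matrix,
    read_sample_sheet,
    write_cq_matrix,
)
from evmir.detection import detection_call, detection_fraction, group_complete
from evmir.diffexp import DEFAULT_ALPHA, DEFAULT_FC
from evmir.normalization import global_mean_normalize, normalizer_set
from evmir.signatures import (
    STANDARD_COMPARISONS,
    build_catalog,
    classify_ev_signatures,
)
from evmir.synthetic_data import SimConfig, generate_cq_dataset


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    cq_path: str | None = None
    sheet_path: str | None = None
    simulate: SimConfig | None = None
    lower_cq: float = 15.0
    upper_cq: float = 30.0
    expressed_cq: float = 28.0
    fc_threshold: float = DEFAULT_FC
    alpha: float = DEFAULT_ALPHA
    comparisons: tuple = STANDARD_COMPARISONS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lower_cq < self.upper_cq <= 40):
            raise ValueError("need 0 < lower_cq < upper_cq <= 40")
        if not (self.expressed_cq < self.upper_cq):
            raise ValueError("expressed_cq must be below upper_cq")
        if self.fc_threshold <= 0 or not (0 < self.alpha <= 1):
            raise ValueError("invalid fc/alpha thresholds")
        has_files = self.cq_path is not None and self.sheet_path is not None
        if not has_files and self.simulate is None:
            raise ValueError("config needs either input paths or a simulation block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        comparisons = raw.pop("comparisons", None)
        kwargs = dict(raw)
        if comparisons is not None:
            kwargs["comparisons"] = tuple(tuple(c) for c in comparisons)
        return cls(simulate=sim, **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig) -> tuple[CqMatrix, SampleSheet]:
    if cfg.simulate is not None:
        cq, sheet, _truth = generate_cq_dataset(cfg.simulate)
        return cq, sheet
    return read_cq_matrix(cfg.cq_path), read_sample_sheet(cfg.sheet_path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, write outputs under ``cfg.out_dir``, return the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cq, sheet = _load_inputs(cfg)
    sheet.validate_against(cq)

    det = detection_call(cq, cfg.lower_cq, cfg.upper_cq)
    det = group_complete(det, sheet)
    norm_ids = normalizer_set(det)
    norm = global_mean_normalize(cq, det, norm_ids)
    catalog = build_catalog(
        norm,
        det,
        sheet,
        comparisons=cfg.comparisons,
        expressed_cq=cfg.expressed_cq,
        fc_threshold=cfg.fc_threshold,
        alpha=cfg.alpha,
    )

    manifest: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[name] = _sha256(path)

    emit("cq_matrix.tsv", lambda p: write_cq_matrix(cq, p))
    emit("sample_sheet.tsv",
         lambda p: sheet.table.to_csv(p, sep="\t", index=False))
    emit("detection.tsv",
         lambda p: det.detected.to_csv(p, sep="\t"))
    emit("normalized.tsv", lambda p: norm.expr.to_csv(p, sep="\t"))
    for key, res in catalog.contrasts.items():
        fname = "contrast_" + key.replace(":", "").replace("|", "_vs_") + ".tsv"
        emit(fname, lambda p, res=res: res.table.to_csv(p, sep="\t"))

    summary: dict = {
        "n_assays": cq.shape[0],
        "n_samples": cq.shape[1],
        "thresholds": {
            "lower_cq": cfg.lower_cq,
            "upper_cq": cfg.upper_cq,
            "expressed_cq": cfg.expressed_cq,
            "fc_threshold": cfg.fc_threshold,
            "alpha": cfg.alpha,
        },
        "detection_fraction": detection_fraction(det),
        "normalizer_set_size": len(norm_ids),
        "comparisons": catalog.counts(),
    }
    ev_keys = {f"{ct}:EV|{ct}:IN" for ct in ("PSC", "NSC", "FPP")}
    if ev_keys <= set(catalog.contrasts):
        sig = classify_ev_signatures(catalog)
        summary["signatures"] = sig.sizes()
        for label, members in (
            ("universal", sig.universal),
            ("universal_enriched", sig.universal_enriched),
            ("shared_neural", sig.shared_neural),
        ):
            emit(
                f"signature_{label}.tsv",
                lambda p, m=members: Path(p).write_text(
                    "\n".join(sorted(m)) + "\n", encoding="utf-8"
                ),
            )
    summary["manifest"] = manifest
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    return summary
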