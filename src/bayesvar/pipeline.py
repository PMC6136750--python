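"""End-to-end orchestration: normalize -> LOOCV (train/predict/classify) -> evaluate."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .errors import InvalidInputError
from .evaluation import evaluate_predictions, loocv_run
from .evidence_lr import profiles_from_table
from .variant_io import normalize_panel, read_variant_table, write_variant_table


def run_pipeline(
    panel_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    evidence_path: str | Path | None = None,
    column_map=None,
    score_columns=None,
    apply_mvp: bool = True,
    add_hotspot: bool = False,
    progress: bool = False,
) -> dict:
    """Run the full pipeline and write normalized.csv, predictions.csv, report.json.

    Each output embeds the config hash and seed.  On a stage failure the
    outputs written so far are renamed with a ``.partial`` suffix and the
    exception is re-raised.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    written: list[Path] = []
    try:
        raw = read_variant_table(panel_path, column_map=column_map)
        panel, score_cols = normalize_panel(
            raw,
            score_columns=score_columns,
            k=config.knn_k,
            per_gene=config.impute_per_gene,
        )
        norm_path = out_dir / "normalized.csv"
        write_variant_table(panel, norm_path, metadata=meta)
        written.append(norm_path)

        profiles = None
        if apply_mvp and evidence_path is not None:
            evidence_path = Path(evidence_path)
            if not evidence_path.exists():
                raise InvalidInputError(f"evidence file not found: {evidence_path}")
            evidence = pd.read_csv(evidence_path, comment="#")
            profiles = profiles_from_table(
                evidence,
                level_map=config.level_map,
                categories=config.evidence_categories,
            )

        predictions = loocv_run(
            panel,
            score_cols,
            config=config,
            evidence_profiles=profiles,
            apply_mvp=apply_mvp,
            add_hotspot=add_hotspot,
            progress=progress,
        )
        pred_path = out_dir / "predictions.csv"
        write_variant_table(predictions, pred_path, metadata=meta)
        written.append(pred_path)

        report = {"metadata": {**meta, "config": config.to_dict()}}
        report["overall"] = evaluate_predictions(predictions).to_dict()
        with_evidence = predictions["evaluable"] & predictions.get(
            "evidence_used", pd.Series(False, index=predictions.index)
        ).fillna(False)
        if with_evidence.any():
            report["with_evidence"] = evaluate_predictions(
                predictions[with_evidence]
            ).to_dict()
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=1))
        written.append(report_path)
        return report
    except Exception:
        for path in written:
            path.rename(path.with_suffix(path.suffix + ".partial"))
        raise
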