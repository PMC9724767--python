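"""Two-stage orchestration of the episignature analysis.

Stage A scores query samples against an *existing* signature and trained
classifier, and embeds queries together with the reference cohorts on
that signature — the "does this case match the known episignature?"
question.  Stage B derives a *new* signature from the cases and their
age/sex-matched controls, validates it by MDS against a background
cohort, and optionally trains a classifier on it.

Both stages are deterministic given their configuration and seed; every
report embeds the seed and a hash of the configuration so outputs are
byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as eio
from . import preprocess
from .classify import (BandThresholds, ClassifierModel, TrainConfig,
                       assign_band, train_classifier)
from .diffmeth import SelectConfig, derive_signature
from .matching import MatchConfig, select_matched_controls
from .mds import classical_mds, euclidean_distances, separation_metrics
from .preprocess import QCConfig

logger = logging.getLogger("episig")


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _prepare_matrix(beta: pd.DataFrame, sheet: pd.DataFrame,
                    control_group: str) -> pd.DataFrame:
    """Impute missing cells from control-group medians if any exist."""
    if not beta.isna().any().any():
        return beta
    controls = sheet.loc[sheet["group"] == control_group, "sample_id"].tolist()
    reference = [c for c in controls if c in beta.columns]
    if not reference:
        reference = list(beta.columns)
    return preprocess.impute_missing(beta, reference)


def _embed_and_score_separation(beta: pd.DataFrame, probe_ids: list[str],
                                sheet: pd.DataFrame, k: int = 2):
    sub = beta.loc[[p for p in probe_ids if p in beta.index]]
    dist = euclidean_distances(sub)
    coords, eigvals = classical_mds(dist, k=k)
    labels = sheet.set_index("sample_id").loc[coords.index, "group"].to_numpy()
    metrics = separation_metrics(coords, labels)
    metrics["eigenvalues_top"] = [float(v) for v in eigvals[: max(k, 5)]]
    return coords, metrics


def run_stage_a(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    signature_probe_ids: list[str],
    model: ClassifierModel,
    query_group: str = "case",
    control_group: str = "control",
    thresholds: BandThresholds | None = None,
    embed_k: int = 2,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Score query samples against an existing signature and classifier.

    Returns a report with per-query ``{sample_id, score, band}``, the MDS
    embedding of all samples on the signature probes, and separation
    metrics.  The reference signature and model are never modified.
    """
    thresholds = thresholds or BandThresholds()
    eio.check_matrix_sheet_consistency(beta, sheet)
    query_ids = sheet.loc[sheet["group"] == query_group, "sample_id"].tolist()
    if not query_ids:
        raise ValueError(f"no samples in query group {query_group!r}")

    beta = _prepare_matrix(beta, sheet, control_group)
    calls = [
        {"sample_id": sid, "score": float(score),
         "band": assign_band(float(score), thresholds)}
        for sid, score in model.score_samples(beta.loc[:, query_ids]).items()
    ]
    coords, metrics = _embed_and_score_separation(
        beta, signature_probe_ids, sheet, embed_k
    )

    report = {
        "stage": "A",
        "seed": seed,
        "config_hash": _config_hash({
            "signature": signature_probe_ids, "model": model.to_dict(),
            "query_group": query_group, "k": embed_k, "seed": seed,
        }),
        "n_signature_probes": len(signature_probe_ids),
        "query_calls": calls,
        "band_counts": {
            band: sum(1 for c in calls if c["band"] == band)
            for band in ("control", "inconclusive", "pathogenic")
        },
        "separation": {k: v for k, v in metrics.items()
                       if k != "silhouette_per_sample"},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        coords.round(10).to_csv(out_dir / "embedding.tsv", sep="\t",
                                index_label="sample_id")
        eio.write_json_report(metrics, out_dir / "metrics.json")
        eio.write_json_report(report, out_dir / "stage_a_report.json")
    logger.info("stage A: %d queries, bands %s", len(calls), report["band_counts"])
    return report


def run_stage_b(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    case_group: str = "case",
    control_group: str = "control",
    background_groups: tuple[str, ...] = ("reference_disorder",),
    control_ids: list[str] | None = None,
    match_cfg: MatchConfig | None = None,
    select_cfg: SelectConfig | None = None,
    qc_cfg: QCConfig | None = None,
    train_cfg: TrainConfig | None = None,
    fit_classifier: bool = False,
    embed_k: int = 2,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Derive a new episignature and validate it against the background.

    Controls are either given explicitly (``control_ids``) or selected by
    greedy age/sex matching from the control group.  The derived
    signature is embedded by MDS together with the background cohort;
    when ``fit_classifier`` is set a nu-SVM is trained on the signature
    (cases positive, everything else negative).

    Returns a report dict; with ``out_dir`` also writes signature.tsv,
    match_table.tsv, embedding.tsv, metrics.json, model.json and
    stage_b_report.json.
    """
    match_cfg = match_cfg or MatchConfig(seed=seed)
    select_cfg = select_cfg or SelectConfig()
    qc_cfg = qc_cfg or QCConfig()
    eio.check_matrix_sheet_consistency(beta, sheet)

    case_ids = sheet.loc[sheet["group"] == case_group, "sample_id"].tolist()
    if not case_ids:
        raise ValueError(f"no samples in case group {case_group!r}")

    match_table = pd.DataFrame(columns=["case_id", "control_id", "age_gap_years"])
    if control_ids is None:
        cases = sheet[sheet["group"] == case_group]
        pool = sheet[sheet["group"] == control_group]
        control_ids, match_table = select_matched_controls(cases, pool, match_cfg)
    logger.info("stage B: %d cases vs %d controls", len(case_ids), len(control_ids))

    beta = _prepare_matrix(beta, sheet, control_group)
    signature = derive_signature(
        beta, sheet, case_ids, control_ids, cfg=select_cfg, qc_cfg=qc_cfg
    )
    logger.info("stage B: signature of %d probes (counts: %s)",
                len(signature), signature.provenance["counts"])

    report: dict = {
        "stage": "B",
        "seed": seed,
        "config_hash": _config_hash({
            "case_ids": case_ids, "control_ids": control_ids,
            "select": asdict(select_cfg), "qc": asdict(qc_cfg),
            "match": asdict(match_cfg), "k": embed_k, "seed": seed,
        }),
        "n_signature_probes": len(signature),
        "stage_counts": signature.provenance["counts"],
        "matched_control_ids": control_ids,
    }

    coords = metrics = None
    if len(signature) >= 1:
        background_ids = sheet.loc[
            sheet["group"].isin(background_groups), "sample_id"
        ].tolist()
        embed_ids = case_ids + control_ids + background_ids
        embed_sheet = sheet[sheet["sample_id"].isin(embed_ids)]
        coords, metrics = _embed_and_score_separation(
            beta.loc[:, embed_ids], signature.probe_ids, embed_sheet, embed_k
        )
        report["separation"] = {k: v for k, v in metrics.items()
                                if k != "silhouette_per_sample"}
    else:
        report["separation"] = None
        report["note"] = "empty signature; no probes passed selection"

    model = None
    if fit_classifier and len(signature) >= 1:
        train_cfg = train_cfg or TrainConfig(seed=seed)
        labels = sheet.set_index("sample_id")["group"] == case_group
        all_ids = list(beta.columns)
        model = train_classifier(
            beta.loc[signature.probe_ids, all_ids],
            labels.loc[all_ids].to_numpy(),
            train_cfg,
        )
        report["classifier"] = {
            "nu": model.nu,
            "test_accuracy": model.provenance["test_accuracy"],
            "cv_accuracy_per_nu": model.provenance["cv_accuracy_per_nu"],
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        eio.write_signature(signature.probes, out_dir / "signature.tsv")
        eio.write_json_report(signature.provenance, out_dir / "provenance.json")
        match_table.to_csv(out_dir / "match_table.tsv", sep="\t", index=False)
        if coords is not None:
            coords.round(10).to_csv(out_dir / "embedding.tsv", sep="\t",
                                    index_label="sample_id")
            eio.write_json_report(metrics, out_dir / "metrics.json")
        if model is not None:
            model.save(out_dir / "model.json")
        eio.write_json_report(report, out_dir / "stage_b_report.json")

    report["_signature"] = signature
    report["_match_table"] = match_table
    if model is not None:
        report["_model"] = model
    return report
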