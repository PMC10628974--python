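"""End-to-end cohort pipeline: composites, scores, evaluation report.

Composes the library stages the way the published analysis ran them: convert
the five-test battery to z-scores and composites at both visits, label each
participant's 5-year trajectory, score the three risk scales at baseline,
then evaluate every scale against the trajectory labels (ROC/AUC with CI,
correlated-AUC comparison, cutoff metrics with likelihood ratios, and OLS
models of CCS change on the total score and on the per-factor profile).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .composite import (DEFAULT_DECLINE_THRESHOLD, CompositeError,
                        composite_for_participant)
from .cohort_io import cohort_to_frame
from .evaluation import (compare_aucs, confusion_at_cutoff, fit_ccs_model,
                         roc_auc)
from .normative import NormativeReference
from .registry import SCALES, ScaleRegistry, default_registry
from .scores import score_scale

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = {"libra": 4.2, "mopards": 4.0, "ppredict": 4.0}


class PipelineError(RuntimeError):
    pass


def score_cohort(cohort, scales=SCALES, missing_policy: str = "omit_factor",
                 registry: Optional[dict[str, ScaleRegistry]] = None,
                 ) -> pd.DataFrame:
    """Score every participant on the requested scales.

    Returns one row per participant with ``<scale>_total``,
    ``<scale>_risk_class`` and per-factor contribution columns
    ``<scale>__<factor>`` (NaN where the factor was omitted for missing
    data).
    """
    reg = registry or default_registry()
    rows = []
    for record, _bl, _y5 in cohort:
        row: dict = {"participant_id": record.participant_id}
        for scale in scales:
            result = score_scale(record, scale, missing_policy, registry=reg)
            row[f"{scale}_total"] = result.total
            row[f"{scale}_risk_class"] = result.risk_class
            for name in reg[scale].factor_names():
                row[f"{scale}__{name}"] = result.profile.contributions.get(name, np.nan)
            if result.profile.omitted:
                logger.info("%s: %s omitted factors: %s", record.participant_id,
                            scale, ",".join(result.profile.omitted))
        rows.append(row)
    return pd.DataFrame(rows)


def compute_composites(cohort, reference: NormativeReference,
                       policy: str = "require_all",
                       threshold: float = DEFAULT_DECLINE_THRESHOLD,
                       ) -> pd.DataFrame:
    """CCS at both visits and the trajectory label per participant.

    Participants whose battery is incomplete under the chosen policy are
    excluded (logged), matching the analysis cohort's requirement of
    complete baseline and follow-up testing.
    """
    rows, dropped = [], []
    for record, baseline, followup in cohort:
        try:
            comp = composite_for_participant(record, baseline, followup,
                                             reference, policy, threshold)
        except CompositeError:
            dropped.append(record.participant_id)
            continue
        rows.append({
            "participant_id": record.participant_id,
            "ccs_baseline": comp.ccs_baseline,
            "ccs_year5": comp.ccs_followup,
            "ccs_change": comp.ccs_change,
            "trajectory": comp.trajectory,
        })
    if dropped:
        logger.warning("excluded %d participant(s) with incomplete batteries: %s",
                       len(dropped), ",".join(dropped[:10]))
    return pd.DataFrame(rows)


def build_scored_table(cohort, reference: NormativeReference,
                       registry: Optional[dict[str, ScaleRegistry]] = None,
                       missing_policy: str = "omit_factor",
                       composite_policy: str = "require_all",
                       threshold: float = DEFAULT_DECLINE_THRESHOLD,
                       ) -> pd.DataFrame:
    """Canonical cohort frame with scores, composites and trajectory appended."""
    base = cohort_to_frame(cohort)
    scores = score_cohort(cohort, registry=registry, missing_policy=missing_policy)
    composites = compute_composites(cohort, reference, composite_policy, threshold)
    merged = base.merge(scores, on="participant_id", how="left")
    return merged.merge(composites, on="participant_id", how="inner")


def _metrics_block(metrics) -> dict:
    return {
        "tp": metrics.tp, "fp": metrics.fp, "tn": metrics.tn, "fn": metrics.fn,
        "sensitivity": metrics.sensitivity, "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "lr_positive": metrics.lr_positive, "lr_negative": metrics.lr_negative,
    }


def evaluate_scored_table(scored: pd.DataFrame,
                          scales=SCALES,
                          cutoffs: Optional[dict[str, float]] = None,
                          registry: Optional[dict[str, ScaleRegistry]] = None,
                          ) -> dict:
    """Full evaluation report for a scored cohort table (JSON-serializable)."""
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    reg = registry or default_registry()
    labels = scored["trajectory"].to_numpy()
    report: dict = {"n": int(len(scored)),
                    "n_decline": int((labels == "decline").sum()),
                    "n_maintain": int((labels == "maintain").sum()),
                    "scales": {}}
    score_vectors = []
    for scale in scales:
        totals = scored[f"{scale}_total"].to_numpy(dtype=float)
        score_vectors.append(totals)
        roc = roc_auc(totals, labels)
        metrics = confusion_at_cutoff(totals, labels, cutoffs[scale])
        block = {
            "cutoff": cutoffs[scale],
            "auc": roc.auc,
            "auc_ci95": list(roc.ci95),
            "metrics": _metrics_block(metrics),
            "regression": {},
        }
        # total-score model, then the per-factor model
        change = scored["ccs_change"].to_numpy(dtype=float)
        total_fit = fit_ccs_model(change, totals, names=[f"{scale}_total"])
        block["regression"]["total"] = _regression_block(total_fit)
        factor_cols = [f"{scale}__{name}" for name in reg[scale].factor_names()]
        design = scored[factor_cols].rename(
            columns={c: c.split("__", 1)[1] for c in factor_cols})
        complete = design.notna().all(axis=1)
        if (~complete).any():
            logger.info("%s per-factor model drops %d row(s) with omitted factors",
                        scale, int((~complete).sum()))
        factor_fit = fit_ccs_model(change[complete.to_numpy()], design[complete])
        block["regression"]["per_factor"] = _regression_block(factor_fit)
        report["scales"][scale] = block
    if len(scales) >= 2:
        chi2, df, p = compare_aucs(np.vstack(score_vectors), labels)
        report["auc_comparison"] = {"chi2": chi2, "df": df, "p": p,
                                    "scales": list(scales)}
    return report


def _regression_block(fit) -> dict:
    return {
        "n": fit.n,
        "r_squared": fit.r_squared,
        "coefficients": {
            name: {"coefficient": s.coefficient, "ci95": list(s.ci95),
                   "p": s.p_value}
            for name, s in fit.predictors.items()
        },
        "dropped": fit.dropped,
    }


def _sha256(path: Optional[Path]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cohort, reference: NormativeReference,
                 outdir, scales=SCALES,
                 cutoffs: Optional[dict[str, float]] = None,
                 registry: Optional[dict[str, ScaleRegistry]] = None,
                 registry_path=None,
                 seed: Optional[int] = None,
                 missing_policy: str = "omit_factor",
                 threshold: float = DEFAULT_DECLINE_THRESHOLD) -> dict:
    """Score, classify and evaluate a cohort; write the three artifacts.

    Writes ``scored.csv``, ``report.json`` (byte-stable given identical
    inputs) and ``manifest.json`` (run provenance, includes a timestamp)
    under ``outdir`` and returns the report.
    """
    if not cohort:
        raise PipelineError("no records in cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scored = build_scored_table(cohort, reference, registry=registry,
                                missing_policy=missing_policy, threshold=threshold)
    if scored.empty:
        raise PipelineError("no scorable participants with complete batteries")
    report = evaluate_scored_table(scored, scales=scales, cutoffs=cutoffs,
                                   registry=registry)
    scored.to_csv(outdir / "scored.csv", index=False)
    report_text = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_text + "\n")
    manifest = {
        "command_line": " ".join(sys.argv),
        "package_version": __version__,
        "seed": seed,
        "registry_sha256": _sha256(registry_path),
        "report_sha256": hashlib.sha256(report_text.encode()).hexdigest(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": ["scored.csv", "report.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
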