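"""End-to-end orchestration: fit → score → evaluate, plus cohort comparison.

These functions back the CLI but are importable directly; every run writes a
config snapshot and seed so it can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import QCConfig
from .errors import DataError, InsufficientDataError
from .features import extract_features
from .mask import BrainMask, iter_mask_dir, load_mask
from .metrics import (
    EvalRecord,
    confusion_summary,
    dice,
    hd95,
    outcome_label,
    pass_rate_table,
    sanity_label,
)
from .model import MaskQC, fit_baseline, save_model
from .scoring import QCScore, score_masks

__all__ = [
    "fit_from_dir",
    "scores_to_frame",
    "evaluate_pairs",
    "run_pipeline",
    "compare_cohorts",
]

logger = logging.getLogger("maskqc")

SCORE_COLUMNS = ["mask_id", "d_min", "d_bar", "r", "verdict", "error"]
EVAL_COLUMNS = ["mask_id", "dice", "hd95", "sanity_positive", "verdict", "outcome"]


def fit_from_dir(baseline_dir, config: QCConfig | None = None) -> MaskQC:
    """Extract features from every mask in a directory and fit the baseline."""
    config = config or QCConfig()
    features = []
    for mask in iter_mask_dir(baseline_dir):
        t0 = time.perf_counter()
        try:
            features.append(extract_features(mask, config.features))
        except DataError as exc:
            logger.warning("skipping baseline mask %s: %s", mask.identifier, exc)
            continue
        logger.info("features(%s): %.1f ms", mask.identifier, 1e3 * (time.perf_counter() - t0))
    if not features:
        raise DataError(f"no readable baseline masks in {baseline_dir}")
    return fit_baseline(features, config)


def scores_to_frame(scores: Sequence[QCScore]) -> pd.DataFrame:
    rows = [
        {
            "mask_id": s.mask_id,
            "d_min": s.d_min,
            "d_bar": s.d_bar,
            "r": s.r,
            "verdict": s.verdict,
            "error": s.error or "",
        }
        for s in scores
    ]
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def evaluate_pairs(
    pairs: Iterable[tuple[BrainMask, BrainMask]],
    scores: Mapping[str, QCScore],
) -> list[EvalRecord]:
    """Dice/HD95 of (candidate, ground-truth) pairs joined with QC verdicts.

    The sanity label marks a candidate as an expected QC failure when its
    Dice against ground truth falls below 0.95 or its HD95 exceeds 15 mm.
    """
    records = []
    for candidate, truth in pairs:
        d = dice(candidate, truth)
        h = hd95(candidate, truth)
        verdict = scores[candidate.identifier].verdict
        records.append(EvalRecord(candidate.identifier, d, h, sanity_label(d, h), verdict))
    return records


def run_pipeline(
    config: QCConfig,
    baseline_dir,
    test_dir,
    out_dir,
    pairs_csv=None,
) -> dict:
    """Fit the baseline, score the test masks, and (given ground-truth pairs)
    evaluate against the sanity set.

    Writes ``model.json``, ``scores.csv``, ``run_log.json`` and — when
    ``pairs_csv`` is given — ``eval.csv`` and ``summary.json`` into
    ``out_dir``. Returns the bundle as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = fit_from_dir(baseline_dir, config)
    save_model(model, out_dir / "model.json")

    test_masks = list(iter_mask_dir(test_dir))
    if not test_masks:
        raise DataError(f"no readable masks in {test_dir}")
    scores = score_masks(test_masks, model)
    scores_df = scores_to_frame(scores)
    scores_df.to_csv(out_dir / "scores.csv", index=False)

    bundle: dict = {"model": model, "scores": scores_df}
    summary: dict = {
        "config": config.model_dump(mode="json"),
        "n_baseline": int(model.clusters_.sizes.sum()),
        "n_test": len(test_masks),
        "chosen_k": model.k_,
        "t_min": model.t_min_,
        "t_mu": model.t_mu_,
    }

    if pairs_csv is not None:
        by_id = {s.mask_id: s for s in scores}
        mask_by_id = {m.identifier: m for m in test_masks}
        pairs_df = pd.read_csv(pairs_csv)
        pair_list = []
        groups: dict[str, list] = {}
        group_cols = [c for c in pairs_df.columns if c not in ("candidate", "ground_truth")]
        for _, row in pairs_df.iterrows():
            cand_path = Path(row["candidate"])
            cand_id = cand_path.name.removesuffix(".gz").removesuffix(".nii")
            candidate = mask_by_id.get(cand_id) or load_mask(cand_path)
            truth = load_mask(row["ground_truth"])
            pair_list.append((candidate, truth))
            key = tuple(row[c] for c in group_cols) if group_cols else ("all",)
            groups.setdefault(key, []).append(by_id[candidate.identifier])
        records = evaluate_pairs(pair_list, by_id)
        eval_df = pd.DataFrame(
            [
                {
                    "mask_id": r.mask_id,
                    "dice": r.dice,
                    "hd95": r.hd95,
                    "sanity_positive": r.sanity_positive,
                    "verdict": r.verdict,
                    "outcome": r.outcome,
                }
                for r in records
            ],
            columns=EVAL_COLUMNS,
        )
        eval_df.to_csv(out_dir / "eval.csv", index=False)
        conf = confusion_summary(records)
        rates = pass_rate_table(groups)
        summary["confusion"] = conf.to_dict()
        summary["pass_rate"] = {"/".join(map(str, k)): v for k, v in rates.items()}
        bundle["eval"] = eval_df
        bundle["confusion"] = conf

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"config": config.model_dump(mode="json"), "seed": config.seed}, fh, indent=2)
    bundle["summary"] = summary
    return bundle


def compare_cohorts(model: MaskQC, cohort: Sequence[BrainMask], bins: int = 20) -> dict:
    """r-score distribution of a held-out cohort under a fitted model.

    Beyond pass/fail QC this is the out-of-distribution screening use: a
    cohort whose shapes drift away from the baseline shifts its whole r
    distribution upward. Returns histogram-ready r values plus summary
    statistics.
    """
    cohort = list(cohort)
    if not cohort:
        raise InsufficientDataError("empty cohort")
    scores = score_masks(cohort, model)
    r = np.array([s.r for s in scores if s.error is None])
    if r.size == 0:
        raise InsufficientDataError("no scorable masks in cohort")
    counts, edges = np.histogram(r, bins=bins, range=(0.0, 1.0))
    return {
        "n": len(cohort),
        "n_scored": int(r.size),
        "r_values": r.tolist(),
        "median_r": float(np.median(r)),
        "mean_r": float(r.mean()),
        "fraction_pass": float(np.mean(r <= model.r_max)),
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }
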