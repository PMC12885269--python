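"""Construct validity of the prompt-scored features.

Features with an external reference are checked by Spearman rank correlation
on training-set participants: the eight clinical-symptom scores against the
corresponding PHQ-8 item responses, and the four referenced linguistic scores
(positive/negative tone, self-focus, present-focus) against lexicon-based
metrics computed from the participant's own words.  p-values are
Benjamini–Hochberg adjusted jointly across all linked features.  Emotion
differentiation and the cognitive distortions have no established reference
metric and are skipped.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import LabelRecord
from .interpret import fdr_adjust
from .lexicon import LinguisticMetrics
from .prompting import FeatureMatrix
from .questions import QuestionSet


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    Returns (nan, nan) when either input is constant — undefined, flagged by
    the caller, never coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _metrics_frame(metrics: Sequence[LinguisticMetrics] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics.set_index("participant_id") if "participant_id" in metrics else metrics
    return pd.DataFrame([m.as_dict() for m in metrics]).set_index("participant_id")


def validity_report(
    fm: FeatureMatrix,
    labels: Sequence[LabelRecord],
    metrics: Sequence[LinguisticMetrics] | pd.DataFrame | None,
    qs: QuestionSet,
) -> pd.DataFrame:
    """One row per reference-linked question: Spearman rho, p, BH-FDR q, n.

    Questions linked to a PHQ-8 item require item-level labels; when those are
    absent the row is flagged ``unavailable`` and excluded from the FDR
    adjustment (which runs jointly across all rows that could be computed).
    """
    by_id = {r.participant_id: r for r in labels}
    met = _metrics_frame(metrics) if metrics is not None else None
    rows = []
    for q in qs.questions:
        ref = q.reference_metric
        if ref is None:
            continue
        scores, refs = [], []
        status = "ok"
        for pid in fm.participant_ids:
            value = fm.data.at[pid, q.qid]
            if pd.isna(value):
                continue
            if ref.startswith("phq8_item_"):
                item = int(ref.removeprefix("phq8_item_"))
                rec = by_id.get(pid)
                if rec is None or rec.phq8_items is None:
                    status = "unavailable"
                    break
                refs.append(rec.phq8_items[item - 1])
            else:
                if met is None or pid not in met.index or pd.isna(met.at[pid, ref]):
                    status = "unavailable"
                    break
                refs.append(float(met.at[pid, ref]))
            scores.append(int(value))
        if status == "unavailable" or len(scores) < 3:
            rows.append({"qid": q.qid, "reference": ref, "rho": np.nan,
                         "p": np.nan, "n": len(scores), "status": "unavailable"})
            continue
        rho, p = spearman_rho(scores, refs)
        status = "constant" if math.isnan(rho) else "ok"
        rows.append({"qid": q.qid, "reference": ref, "rho": rho, "p": p,
                     "n": len(scores), "status": status})
    report = pd.DataFrame(rows)
    report["q"] = np.nan
    ok = report["status"] == "ok"
    if ok.any():
        report.loc[ok, "q"] = fdr_adjust(report.loc[ok, "p"].to_numpy())
    return report
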