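"""Pixel-level per-class F1 scoring and per-scanner aggregation.

For every case, prediction and ground-truth masks are compared pixel by pixel
(pooled over all the case's ROIs); each class is scored one-vs-rest as
``F1 = 2TP / (2TP + FP + FN)``, which at pixel level equals the Dice overlap.
Pixels labeled "uncertain" in the truth are excluded from every count.  The
headline score of a case is the cancer-class F1 (the quantity of clinical
interest is residual cancer); a macro mean over the defined classes is also
reported.  A class absent from both truth and prediction has an undefined F1
and is excluded from means rather than scored 0 or 1.

Per-scanner summaries report the mean headline F1 over cases with a t-based
95% confidence interval (``mean +/- t(n-1, 0.975) * SD / sqrt(n)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rpcseg.taxonomy import CANCER, IGNORE, TARGET_CODES


@dataclass
class CaseScore:
    """Per-class confusion counts and F1 scores for one case."""

    case_id: str
    scanner_type: str = ""
    tp: dict[int, int] = field(default_factory=dict)
    fp: dict[int, int] = field(default_factory=dict)
    fn: dict[int, int] = field(default_factory=dict)

    def f1(self, cls: int) -> float:
        """One-vs-rest F1 for a class; NaN when the class is absent from both masks."""
        denom = 2 * self.tp[cls] + self.fp[cls] + self.fn[cls]
        if denom == 0:
            return float("nan")
        return 2.0 * self.tp[cls] / denom

    @property
    def headline_f1(self) -> float:
        return self.f1(CANCER)

    @property
    def macro_f1(self) -> float:
        vals = [self.f1(c) for c in TARGET_CODES]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


def score_case(
    predictions: np.ndarray | Sequence[np.ndarray],
    truths: np.ndarray | Sequence[np.ndarray],
    case_id: str = "",
    scanner_type: str = "",
) -> CaseScore:
    """Score one case from aligned (prediction, truth) mask pairs.

    Accepts a single pair or parallel sequences of pairs (all the case's
    ROIs, pooled at pixel level).  Ignore pixels in the truth are dropped
    from every numerator and denominator.
    """
    if isinstance(predictions, np.ndarray):
        predictions, truths = [predictions], [truths]  # type: ignore[list-item]
    score = CaseScore(case_id=case_id, scanner_type=scanner_type,
                      tp={c: 0 for c in TARGET_CODES},
                      fp={c: 0 for c in TARGET_CODES},
                      fn={c: 0 for c in TARGET_CODES})
    for pred, truth in zip(predictions, truths, strict=True):
        pred, truth = np.asarray(pred), np.asarray(truth)
        if pred.shape != truth.shape:
            raise ValueError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
        keep = truth != IGNORE
        p, t = pred[keep], truth[keep]
        for c in TARGET_CODES:
            pc, tc = p == c, t == c
            score.tp[c] += int(np.count_nonzero(pc & tc))
            score.fp[c] += int(np.count_nonzero(pc & ~tc))
            score.fn[c] += int(np.count_nonzero(~pc & tc))
    return score


@dataclass
class ScannerSummary:
    """Mean headline F1 of one scanner's test cases with a 95% t-interval."""

    scanner_type: str
    n_cases: int
    mean_f1: float
    ci_lower: float
    ci_upper: float
    sd: float
    per_class_mean: dict[int, float]
    has_ci: bool = True

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n_cases)


def summarize_scanner(scores: Sequence[CaseScore],
                      scanner_type: str | None = None,
                      level: float = 0.95) -> ScannerSummary:
    """Aggregate per-case headline F1s into a per-scanner mean and t-based CI.

    Cases whose headline F1 is undefined (cancer absent from both masks) are
    excluded.  With fewer than two usable cases the summary carries no CI and
    is flagged via ``has_ci=False``.
    """
    if not scores:
        raise ValueError("no case scores to summarize")
    scanner = scanner_type or scores[0].scanner_type
    vals = np.array([s.headline_f1 for s in scores], dtype=float)
    vals = vals[~np.isnan(vals)]
    per_class = {}
    for c in TARGET_CODES:
        cv = np.array([s.f1(c) for s in scores], dtype=float)
        cv = cv[~np.isnan(cv)]
        per_class[c] = float(cv.mean()) if cv.size else float("nan")
    n = int(vals.size)
    mean = float(vals.mean()) if n else float("nan")
    if n < 2:
        return ScannerSummary(scanner, n, mean, float("nan"), float("nan"),
                              float("nan"), per_class, has_ci=False)
    sd = float(vals.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
    return ScannerSummary(scanner, n, mean, mean - half, mean + half, sd, per_class)


def scores_to_csv(scores: Sequence[CaseScore], path: str | Path) -> None:
    rows = []
    for s in scores:
        row = {"case_id": s.case_id, "scanner_type": s.scanner_type,
               "headline_f1": s.headline_f1, "macro_f1": s.macro_f1}
        for c in TARGET_CODES:
            row[f"f1_{c}"] = s.f1(c)
            row[f"tp_{c}"], row[f"fp_{c}"], row[f"fn_{c}"] = s.tp[c], s.fp[c], s.fn[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def summaries_to_csv(summaries: Sequence[ScannerSummary], path: str | Path) -> None:
    rows = [{"scanner_type": s.scanner_type, "n_cases": s.n_cases,
             "mean_f1": s.mean_f1, "ci_lower": s.ci_lower, "ci_upper": s.ci_upper,
             "sd": s.sd, "has_ci": s.has_ci,
             **{f"mean_f1_class_{c}": s.per_class_mean.get(c) for c in TARGET_CODES}}
            for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False)
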