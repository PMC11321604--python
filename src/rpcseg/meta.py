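"""Leave-one-scanner-out cross-validation and random-effects meta-analytic pooling.

In internal-external cross-validation, each scanner type in turn plays the
external cohort: the model is trained on all cases from the other scanners
and tested on the held-out scanner's cases.  The per-scanner mean F1 scores
(with standard errors) are then pooled with a random-effects model:

* between-study variance ``tau^2`` by iterative restricted maximum
  likelihood (Fisher scoring, tolerance 1e-10, at most 100 iterations,
  floored at 0);
* pooled mean ``mu = sum(w_i y_i) / sum(w_i)`` with inverse-variance weights
  ``w_i = 1 / (se_i^2 + tau^2)``;
* a Hartung-Knapp-Sidik-Jonkman confidence interval,
  ``mu +/- t(k-1) * sqrt(sum(w_i (y_i - mu)^2) / ((k-1) sum(w_i)))``, with the
  Jackson-style safeguard that the interval is never narrower than the
  z-based Wald random-effects interval;
* heterogeneity as Cochran's Q, and ``I^2 = 100 tau^2 / (tau^2 + s^2)`` with
  the typical within-study variance
  ``s^2 = (k-1) sum(u_i) / ((sum u_i)^2 - sum(u_i^2))``, ``u_i = 1/se_i^2``;
  Q-profile confidence intervals for ``tau^2`` and ``I^2``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rpcseg.evaluate import CaseScore, ScannerSummary, score_case, summarize_scanner
from rpcseg.patches import PatchSpec, build_patchset
from rpcseg.stitch import StitchSpec, predict_roi
from rpcseg.taxonomy import CohortManifest
from rpcseg.train import TrainConfig, TrainedModel, train


# ---------------------------------------------------------------------------
# study inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyInput:
    """One study (here: one scanner's cross-validation) for pooling."""

    label: str
    effect: float
    se: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: se must be > 0, got {self.se}")


def ci_to_se(mean: float, lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error reconstructed from a symmetric normal confidence interval.

    ``se = (upper - lower) / (2 z)`` with z the normal quantile of the level.
    """
    if lower > upper:
        raise ValueError(f"inverted CI bounds: ({lower}, {upper})")
    if not (lower <= mean <= upper):
        warnings.warn(f"mean {mean} outside its CI ({lower}, {upper})", stacklevel=2)
    z = stats.norm.ppf(0.5 + level / 2)
    return (upper - lower) / (2 * z)


def read_studies_csv(path: str | Path) -> list[StudyInput]:
    """Read study rows from CSV with columns label, effect, and se or lower/upper."""
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        try:
            label = str(row["label"])
            effect = float(row["effect"])
            if "se" in df.columns and not pd.isna(row.get("se")):
                se = float(row["se"])
            else:
                se = ci_to_se(effect, float(row["lower"]), float(row["upper"]))
            n = int(row["n"]) if "n" in df.columns and not pd.isna(row.get("n")) else None
            out.append(StudyInput(label, effect, se, n))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed study row {i} ({dict(row)}): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# REML + HKSJ pooling
# ---------------------------------------------------------------------------

def _reml_score_info(tau2: float, y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """REML score and expected information for the intercept-only model."""
    w = 1.0 / (v + tau2)
    sw = w.sum()
    # P = diag(w) - w w^T / sw   (projection for X = 1)
    mu = (w * y).sum() / sw
    r = y - mu
    tr_p = sw - (w ** 2).sum() / sw
    py = w * r                       # P y
    ppy = w * py - w * (w * py).sum() / sw   # P P y
    score = -0.5 * tr_p + 0.5 * float(y @ ppy)
    tr_pp = (w ** 2).sum() - 2 * (w ** 3).sum() / sw + ((w ** 2).sum() / sw) ** 2
    return score, 0.5 * tr_pp


def reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10,
              max_iter: int = 100) -> float:
    """Between-study variance by iterative REML (Fisher scoring, floored at 0)."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if k < 2:
        return 0.0
    tau2 = max(float(np.var(y, ddof=1) - v.mean()), 0.0)
    for _ in range(max_iter):
        score, info = _reml_score_info(tau2, y, v)
        if tau2 == 0.0 and score < 0:
            return 0.0
        step = score / info
        new = tau2 + step
        # step-halve into the feasible region
        halvings = 0
        while new < 0 and halvings < 60:
            step /= 2
            new = tau2 + step
            halvings += 1
        new = max(new, 0.0)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    # Fisher scoring failed to settle; fall back to a bracketed root of the score
    hi = max(tau2, v.max(), 1e-8) * 10
    if _reml_score_info(0.0, y, v)[0] < 0:
        return 0.0
    while _reml_score_info(hi, y, v)[0] > 0 and hi < 1e8:
        hi *= 10
    return float(optimize.brentq(lambda t: _reml_score_info(t, y, v)[0], 0.0, hi,
                                 xtol=tol))


def _generalized_q(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = (w * y).sum() / w.sum()
    return float((w * (y - mu) ** 2).sum())


def _qprofile_ci(y: np.ndarray, v: np.ndarray,
                 level: float = 0.95) -> tuple[float, float]:
    """Q-profile confidence interval for tau^2."""
    k = y.size
    alpha = 1 - level
    q_hi = stats.chi2.ppf(1 - alpha / 2, k - 1)
    q_lo = stats.chi2.ppf(alpha / 2, k - 1)
    upper_cap = max(v.max(), np.var(y, ddof=1) if k > 1 else 1.0, 1e-8) * 1e3

    def solve(target: float) -> float:
        if _generalized_q(0.0, y, v) <= target:
            return 0.0
        if _generalized_q(upper_cap, y, v) >= target:
            return float("inf")
        return float(optimize.brentq(
            lambda t: _generalized_q(t, y, v) - target, 0.0, upper_cap))

    return solve(q_hi), solve(q_lo)


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    mu: float
    ci_lower: float
    ci_upper: float
    se_mu: float
    tau2: float
    tau2_ci: tuple[float, float]
    i2: float
    i2_ci: tuple[float, float]
    q: float
    weights: dict[str, float]
    k: int
    level: float = 0.95

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tau2_ci"] = list(self.tau2_ci)
        d["i2_ci"] = list(self.i2_ci)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def meta_pool(studies: Sequence[StudyInput], level: float = 0.95) -> MetaResult:
    """Random-effects pooling with REML tau^2 and an HKSJ-Jackson interval.

    With a single study the inputs are passed through with a warning; any
    non-positive standard error raises at study construction.
    """
    k = len(studies)
    if k == 0:
        raise ValueError("no studies to pool")
    y = np.array([s.effect for s in studies], dtype=float)
    v = np.array([s.se ** 2 for s in studies], dtype=float)
    labels = [s.label for s in studies]
    if k == 1:
        warnings.warn("single study: passthrough, no pooling", stacklevel=2)
        z = stats.norm.ppf(0.5 + level / 2)
        return MetaResult(float(y[0]), float(y[0] - z * studies[0].se),
                          float(y[0] + z * studies[0].se), studies[0].se,
                          0.0, (0.0, float("inf")), 0.0, (0.0, 100.0),
                          0.0, {labels[0]: 1.0}, 1, level)

    tau2 = reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    sw = w.sum()
    mu = float((w * y).sum() / sw)
    se_wald = float(np.sqrt(1.0 / sw))

    # HKSJ variance: weighted residual variance of mu with k-1 df
    q_hk = float((w * (y - mu) ** 2).sum() / (k - 1))
    se_hk = float(np.sqrt(q_hk / sw))
    t_q = stats.t.ppf(0.5 + level / 2, k - 1)
    z_q = stats.norm.ppf(0.5 + level / 2)
    half = max(t_q * se_hk, z_q * se_wald)  # Jackson-style safeguard

    # heterogeneity on fixed-effect weights
    u = 1.0 / v
    q_stat = _generalized_q(0.0, y, v)
    s2 = float((k - 1) * u.sum() / (u.sum() ** 2 - (u ** 2).sum()))
    i2 = 100.0 * tau2 / (tau2 + s2)
    t_lo, t_hi = _qprofile_ci(y, v, level)
    i2_ci = (100.0 * t_lo / (t_lo + s2),
             100.0 if np.isinf(t_hi) else 100.0 * t_hi / (t_hi + s2))

    return MetaResult(
        mu=mu, ci_lower=mu - half, ci_upper=mu + half, se_mu=se_hk,
        tau2=tau2, tau2_ci=(t_lo, t_hi), i2=i2, i2_ci=i2_ci, q=q_stat,
        weights={lab: float(wi / sw) for lab, wi in zip(labels, w)},
        k=k, level=level,
    )


def forest_data(studies: Sequence[StudyInput], result: MetaResult,
                level: float = 0.95) -> pd.DataFrame:
    """Per-study effects, CIs and pooled weights plus the pooled diamond row."""
    z = stats.norm.ppf(0.5 + level / 2)
    rows = [{"label": s.label, "effect": s.effect,
             "lower": s.effect - z * s.se, "upper": s.effect + z * s.se,
             "weight": result.weights[s.label], "kind": "study"} for s in studies]
    rows.append({"label": "pooled", "effect": result.mu, "lower": result.ci_lower,
                 "upper": result.ci_upper, "weight": 1.0, "kind": "diamond"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leave-one-scanner-out cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    test_scanner: str
    train_cases: tuple[str, ...]
    test_cases: tuple[str, ...]


@dataclass(frozen=True)
class CrossValPlan:
    """One fold per scanner type plus the ablation switches for the run."""

    folds: tuple[Fold, ...]
    normalize: bool = True
    augment: bool = True

    @classmethod
    def from_manifest(cls, manifest: CohortManifest,
                      normalize: bool = True, augment: bool = True) -> "CrossValPlan":
        folds = []
        for scanner in manifest.scanners():
            test = tuple(e.case_id for e in manifest.by_scanner(scanner))
            train_ = tuple(e.case_id for e in manifest.entries
                           if e.scanner_type != scanner)
            if not test:
                warnings.warn(f"scanner {scanner} has no test cases; fold skipped",
                              stacklevel=2)
                continue
            folds.append(Fold(scanner, train_, test))
        return cls(tuple(folds), normalize=normalize, augment=augment)

    def validate(self) -> None:
        for f in self.folds:
            overlap = set(f.train_cases) & set(f.test_cases)
            if overlap:
                raise ValueError(f"fold {f.test_scanner}: cases in both splits: {overlap}")


@dataclass
class CrossValResult:
    fold_summaries: list[ScannerSummary]
    case_scores: list[CaseScore]
    meta: MetaResult | None
    final_model: TrainedModel | None = None

    def studies(self) -> list[StudyInput]:
        return [StudyInput(s.scanner_type, s.mean_f1, s.se, s.n_cases)
                for s in self.fold_summaries if s.has_ci and s.sd > 0]


def run_crossval(
    manifest: CohortManifest,
    root: str | Path,
    train_config: TrainConfig | None = None,
    patch_spec: PatchSpec | None = None,
    stitch_spec: StitchSpec | None = None,
    plan: CrossValPlan | None = None,
    train_final: bool = True,
) -> CrossValResult:
    """Run leave-one-scanner-out internal-external cross-validation.

    For each fold, a patch set is built from the training scanners' cases,
    a model is trained, and every held-out case is predicted by stitched
    inference and scored.  The per-fold per-scanner summaries are pooled with
    :func:`meta_pool` (when at least two folds yield usable summaries), and a
    final model is trained on all cases unless ``train_final`` is False.
    """
    train_config = train_config or TrainConfig()
    patch_spec = patch_spec or PatchSpec()
    stitch_spec = stitch_spec or StitchSpec()
    plan = plan or CrossValPlan.from_manifest(manifest)
    plan.validate()
    if len(plan.folds) < 2:
        raise ValueError("need >= 2 scanner types with cases for cross-validation")
    config = dataclasses.replace(train_config, normalize=plan.normalize,
                                 augment=plan.augment)

    rois = {e.case_id: manifest.load_roi(e, root) for e in manifest.entries}
    masks = {cid: roi.mask for cid, roi in rois.items()}

    summaries: list[ScannerSummary] = []
    all_scores: list[CaseScore] = []
    for fold in plan.folds:
        patchset = build_patchset({cid: masks[cid] for cid in fold.train_cases},
                                  patch_spec, seed=config.seed)
        model = train(patchset, rois, config)
        fold_scores = []
        for cid in fold.test_cases:
            pred = predict_roi(model, rois[cid].image, stitch_spec)
            fold_scores.append(score_case(pred.labels, rois[cid].mask, case_id=cid,
                                          scanner_type=fold.test_scanner))
        summaries.append(summarize_scanner(fold_scores, fold.test_scanner))
        all_scores.extend(fold_scores)

    result = CrossValResult(summaries, all_scores, meta=None)
    studies = result.studies()
    if len(studies) >= 2:
        result.meta = meta_pool(studies)
    if train_final:
        patchset = build_patchset(masks, patch_spec, seed=config.seed)
        result.final_model = train(patchset, rois, config)
    return result
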