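"""LOOCV harness, confusion tabulation, performance statistics and AUC tests.

Sensitivity and specificity follow the convention that the denominators
count *all evaluated* variants of the relevant truth side, including those
predicted VUS — indecision is penalised.  PPV/NPV/accuracy are computed
over definitive calls only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm, rankdata

from .classify import assign_class, credible_interval
from .config import RunConfig
from .errors import InsufficientTrainingDataError, InvalidInputError
from .evidence_lr import EvidenceProfile, add_hotspot_evidence, total_lr
from .ivp_model import (
    build_training_set,
    fit_pg_logistic,
    predict_distribution,
    select_predictors,
)
from .mvp_posterior import posterior_update, rescale_prior
from .variant_io import POSITIVE_CLASSES, NEGATIVE_CLASSES


@dataclass
class ConfusionSummary:
    """Definitive-call counts plus VUS tallies split by truth side."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0
    VUS_pos: int = 0
    VUS_neg: int = 0

    @property
    def n_positive_evaluated(self) -> int:
        return self.TP + self.FN + self.VUS_pos

    @property
    def n_negative_evaluated(self) -> int:
        return self.TN + self.FP + self.VUS_neg


@dataclass
class PerformanceReport:
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    ppv: float = float("nan")
    npv: float = float("nan")
    accuracy: float = float("nan")
    auc: float = float("nan")
    p_vus: float = float("nan")
    counts: ConfusionSummary = field(default_factory=ConfusionSummary)

    def to_dict(self) -> dict:
        def _clean(x):
            return None if (x is None or not np.isfinite(x)) else float(x)

        return {
            "sensitivity": _clean(self.sensitivity),
            "specificity": _clean(self.specificity),
            "ppv": _clean(self.ppv),
            "npv": _clean(self.npv),
            "accuracy": _clean(self.accuracy),
            "auc": _clean(self.auc),
            "p_vus": _clean(self.p_vus),
            "counts": {
                "TP": self.counts.TP, "TN": self.counts.TN,
                "FP": self.counts.FP, "FN": self.counts.FN,
                "VUS_pos": self.counts.VUS_pos, "VUS_neg": self.counts.VUS_neg,
            },
        }


def confusion_outcomes(predicted_classes, truth) -> ConfusionSummary:
    """Tally 5-tier predictions against binary truth (1 = pathogenic side)."""
    cs = ConfusionSummary()
    for label, t in zip(predicted_classes, truth):
        if label is None or (isinstance(label, float) and np.isnan(label)):
            raise InvalidInputError("unlabeled prediction in confusion tabulation")
        if t not in (0, 1, 0.0, 1.0, True, False):
            raise InvalidInputError(f"truth values must be binary, got {t!r}")
        positive_call = label in POSITIVE_CLASSES
        negative_call = label in NEGATIVE_CLASSES
        if not positive_call and not negative_call and label != "VUS":
            raise InvalidInputError(f"unknown predicted class {label!r}")
        if bool(t):
            if positive_call:
                cs.TP += 1
            elif negative_call:
                cs.FN += 1
            else:
                cs.VUS_pos += 1
        else:
            if positive_call:
                cs.FP += 1
            elif negative_call:
                cs.TN += 1
            else:
                cs.VUS_neg += 1
    return cs


def _ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else float("nan")


def performance_stats(
    cs: ConfusionSummary, scores=None, truth=None
) -> PerformanceReport:
    """Performance statistics from confusion counts (AUC from scores if given).

    Zero denominators propagate as NaN ("not able to calculate") rather than
    raising.
    """
    n_pos = cs.n_positive_evaluated
    n_neg = cs.n_negative_evaluated
    auc = float("nan")
    if scores is not None and truth is not None:
        auc = auc_rank(scores, truth)
    return PerformanceReport(
        sensitivity=_ratio(cs.TP, n_pos),
        specificity=_ratio(cs.TN, n_neg),
        ppv=_ratio(cs.TP, cs.TP + cs.FP),
        npv=_ratio(cs.TN, cs.TN + cs.FN),
        accuracy=_ratio(cs.TP + cs.TN, cs.TP + cs.TN + cs.FP + cs.FN),
        auc=auc,
        p_vus=_ratio(cs.VUS_pos + cs.VUS_neg, n_pos + n_neg),
        counts=cs,
    )


def auc_rank(scores, truth) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive outscores random negative),
    ties counted half.  NaN when either class is absent."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float).astype(bool)
    m = int(truth.sum())
    n = int((~truth).sum())
    if m == 0 or n == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[truth].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_placements(scores: np.ndarray, truth: np.ndarray):
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(neg)) / m
    return v10, v01


def delong_test(scores_a, scores_b, truth) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs on the same variants.

    Returns (AUC_a - AUC_b, two-sided p-value).  Identical score vectors
    give (0, 1); a degenerate variance estimate gives p = NaN with a warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth, dtype=float).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != truth.shape[0]:
        raise InvalidInputError("score vectors and truth must have the same length")
    if truth.all() or not truth.any():
        raise InvalidInputError("DeLong test needs both classes present")
    if np.array_equal(scores_a, scores_b):
        return 0.0, 1.0
    v10a, v01a = _delong_placements(scores_a, truth)
    v10b, v01b = _delong_placements(scores_b, truth)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = float(auc_a - auc_b)
    if not np.isfinite(var) or var <= 0:
        warnings.warn("degenerate variance in DeLong test; p-value undefined")
        return diff, float("nan")
    z = diff / np.sqrt(var)
    return diff, float(2.0 * norm.sf(abs(z)))


def binomial_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "agresti-coull"
) -> tuple[float, float]:
    """Binomial confidence interval for a proportion.

    Default is Agresti-Coull (which reproduces the reference bounds this
    package is validated against); ``method="clopper-pearson"`` gives the
    exact interval.
    """
    if trials <= 0 or not (0 <= successes <= trials):
        raise InvalidInputError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, trials - successes + 1))
        hi = 1.0 if successes == trials else float(beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes))
        return lo, hi
    if method == "agresti-coull":
        z = norm.ppf(1.0 - alpha / 2.0)
        n_t = trials + z * z
        p_t = (successes + z * z / 2.0) / n_t
        half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
        return float(max(0.0, p_t - half)), float(min(1.0, p_t + half))
    raise InvalidInputError(f"unknown binomial CI method {method!r}")


# ---------------------------------------------------------------------------
# leave-one-out cross validation


def loocv_run(
    panel: pd.DataFrame,
    score_columns,
    config: RunConfig | None = None,
    evidence_profiles: dict[str, EvidenceProfile] | None = None,
    apply_mvp: bool = True,
    add_hotspot: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Leave-one-out predictions over all class-known variants of a panel.

    For each class-known variant the training set for its gene is rebuilt
    from the panel *without* that variant (including any data expansion),
    predictor selection and the Pólya-Gamma fit are redone, the rescaled
    prior is formed and — when the variant carries evidence and
    ``apply_mvp`` — updated into a posterior before 5-tier classification.
    Deterministic given ``config.seed``.
    """
    config = config or RunConfig()
    panel = panel.reset_index(drop=True)
    profiles = dict(evidence_profiles or {})
    if add_hotspot and config.hotspot_level:
        profiles = add_hotspot_evidence(
            profiles, panel, level=config.hotspot_level, level_map=config.level_map
        )
    eligible = panel.index[panel["y"].notna()].tolist()
    children = np.random.SeedSequence(config.seed).spawn(len(eligible))
    records = []
    cats = tuple(config.evidence_categories)
    for pos, idx in enumerate(eligible):
        variant = panel.loc[idx]
        vid = str(variant["variant_id"])
        rng = np.random.default_rng(children[pos])
        rest = panel.drop(index=idx)
        rec = {
            "variant_id": vid,
            "gene": variant["gene"],
            "y_true": float(variant["y"]),
            "evaluable": True,
        }
        try:
            training = build_training_set(
                rest,
                variant["gene"],
                score_columns,
                min_negative=config.min_negative,
                min_positive=config.min_positive,
                descending=config.merge_descending,
            )
            predictors = select_predictors(
                training,
                penalties=config.penalties,
                cv_folds=config.cv_folds,
                seed=config.seed,
            )
            model = fit_pg_logistic(
                training,
                predictors,
                n_samples=config.n_samples,
                burn_in=config.burn_in,
                prior_var=config.prior_var,
                seed=rng,
            )
        except InsufficientTrainingDataError as exc:
            rec.update({"evaluable": False, "error": str(exc)})
            records.append(rec)
            continue
        ivp = predict_distribution(model, variant[list(score_columns)])
        prior = rescale_prior(ivp, clip=config.prior_clip)
        profile = profiles.get(vid, EvidenceProfile()).restricted(cats)
        lr, has_evidence = total_lr(profile)
        use_mvp = apply_mvp and has_evidence
        dist = posterior_update(prior, lr) if use_mvp else prior
        pci = credible_interval(dist, level=config.pci_level, min_samples=min(100, config.n_samples))
        label = assign_class(pci, config.thresholds)
        rec.update(
            {
                "n_train": training.n,
                "n_borrowed": len(training.borrow_log),
                "borrowed_ids": ";".join(v for v, _ in training.borrow_log),
                "predictors": ";".join(predictors),
                "ivp_median": ivp.median,
                "prior_median": prior.median,
                "lr_total": lr,
                "evidence_used": use_mvp,
                "score": dist.median,
                "pci_lower": pci.lower,
                "pci_upper": pci.upper,
                "predicted_class": label,
            }
        )
        records.append(rec)
        if progress and (pos + 1) % 25 == 0:
            print(f"loocv: {pos + 1}/{len(eligible)}", flush=True)
    return pd.DataFrame(records)


def evaluate_predictions(predictions: pd.DataFrame) -> PerformanceReport:
    """Performance report from a LOOCV prediction table (unevaluable rows dropped)."""
    df = predictions[predictions["evaluable"]]
    cs = confusion_outcomes(df["predicted_class"], df["y_true"])
    return performance_stats(cs, scores=df["score"], truth=df["y_true"])
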