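"""Gene-specific in silico prediction models.

Pipeline per gene: build a training set (borrowing variants from the most
similar genes when the gene's own class-known variants are too few), select
a predictor subset by penalised bidirectional stepwise logistic regression,
and fit a Bayesian logistic regression by Pólya-Gamma Gibbs sampling.  The
fitted model yields, for any variant, a Monte-Carlo distribution of
pathogenicity probabilities (one inverse-logit per retained coefficient
sample).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .errors import InsufficientTrainingDataError, InvalidInputError, SamplerError
from .pg import draw_pg1
from .variant_io import NEGATIVE_CLASSES, POSITIVE_CLASSES

_PROB_EPS = 1e-12


@dataclass
class ProbabilityDistribution:
    """Monte-Carlo samples of a pathogenicity probability for one variant."""

    samples: np.ndarray
    role: str = "ivp"  # ivp | prior | posterior

    def __post_init__(self) -> None:
        self.samples = np.clip(
            np.asarray(self.samples, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS
        )

    @property
    def median(self) -> float:
        return float(np.median(self.samples))


@dataclass
class TrainingSet:
    """Training variants for one gene, possibly expanded from donor genes."""

    gene: str
    variant_ids: list[str]
    X: np.ndarray  # (n, n_predictors) unit-scaled scores
    y: np.ndarray  # binary response
    predictor_names: list[str]
    n_negative: float
    n_positive: float
    borrow_log: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, donor gene)

    @property
    def n(self) -> int:
        return len(self.variant_ids)


@dataclass
class IVPModel:
    """Selected predictors plus joint posterior coefficient samples."""

    gene: str
    predictors: list[str]
    coef_samples: np.ndarray  # (N, K+1), column 0 = intercept
    settings: dict = field(default_factory=dict)
    borrow_log: list[tuple[str, str]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Write model metadata as JSON with the coefficient samples inline."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "gene": self.gene,
            "predictors": self.predictors,
            "settings": self.settings,
            "borrow_log": [list(t) for t in self.borrow_log],
            "coef_samples": self.coef_samples.tolist(),
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "IVPModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene=payload["gene"],
            predictors=list(payload["predictors"]),
            coef_samples=np.asarray(payload["coef_samples"], dtype=float),
            settings=payload.get("settings", {}),
            borrow_log=[tuple(t) for t in payload.get("borrow_log", [])],
        )


def effective_counts(classes: Iterable[str]) -> tuple[float, float]:
    """(n_negative, n_positive) with benign/pathogenic at weight 1, VLB/VLP at 0.5."""
    classes = pd.Series(list(classes))
    n_neg = float((classes == "benign").sum()) + 0.5 * float((classes == "VLB").sum())
    n_pos = float((classes == "pathogenic").sum()) + 0.5 * float((classes == "VLP").sum())
    return n_neg, n_pos


def gene_distance(
    panel: pd.DataFrame, gene_g: str, gene_h: str, score_columns: Sequence[str]
) -> float:
    """Mean Euclidean distance over all cross-gene pairs of class-known variants."""
    known = panel[panel["y"].notna()]
    xg = known.loc[known["gene"] == gene_g, list(score_columns)].to_numpy(dtype=float)
    xh = known.loc[known["gene"] == gene_h, list(score_columns)].to_numpy(dtype=float)
    if xg.shape[0] == 0 or xh.shape[0] == 0:
        raise InvalidInputError(
            f"gene distance needs class-known variants in both genes ({gene_g}, {gene_h})"
        )
    return float(cdist(xg, xh).mean())


def build_training_set(
    panel: pd.DataFrame,
    gene: str,
    score_columns: Sequence[str],
    min_negative: float = 5.0,
    min_positive: float = 5.0,
    descending: bool = True,
) -> TrainingSet:
    """Training data for ``gene``, expanded from similar genes if needed.

    If the gene's own class-known variants already satisfy the effective
    minima no borrowing occurs.  Otherwise donor genes are visited in
    ascending order of mean cross-gene distance and, within a donor,
    variants of the deficient class side are merged one by one ordered by
    their mean distance to the gene's own variants (descending by default,
    as specified; ``descending=False`` merges most-similar first).
    """
    cols = list(score_columns)
    known = panel[panel["y"].notna()]
    own = known[known["gene"] == gene]
    if own.empty:
        raise InvalidInputError(f"gene {gene!r} has no class-known variants")

    n_neg, n_pos = effective_counts(own["consensus_class"])
    ids = [str(v) for v in own["variant_id"]]
    rows = [own]
    borrow_log: list[tuple[str, str]] = []

    if n_neg < min_negative or n_pos < min_positive:
        own_X = own[cols].to_numpy(dtype=float)
        donors = []
        for other in sorted(known.loc[known["gene"] != gene, "gene"].unique()):
            donors.append((gene_distance(panel, gene, other, cols), other))
        donors.sort()
        for _, donor in donors:
            if n_neg >= min_negative and n_pos >= min_positive:
                break
            dv = known[known["gene"] == donor].copy()
            d = cdist(dv[cols].to_numpy(dtype=float), own_X).mean(axis=1)
            dv = dv.assign(_dist=d).sort_values(
                ["_dist", "variant_id"], ascending=[not descending, True]
            )
            for row in dv.itertuples(index=False):
                cls = row.consensus_class
                is_pos = cls in POSITIVE_CLASSES
                is_neg = cls in NEGATIVE_CLASSES
                weight = 1.0 if cls in ("benign", "pathogenic") else 0.5
                if is_neg and n_neg < min_negative:
                    n_neg += weight
                elif is_pos and n_pos < min_positive:
                    n_pos += weight
                else:
                    continue
                ids.append(str(row.variant_id))
                borrow_log.append((str(row.variant_id), donor))
                if n_neg >= min_negative and n_pos >= min_positive:
                    break
            rows.append(known[known["variant_id"].astype(str).isin(
                [v for v, g in borrow_log if g == donor]
            )])
        if n_neg < min_negative or n_pos < min_positive:
            raise InsufficientTrainingDataError(
                f"gene {gene!r}: training minima unreachable after expansion "
                f"(n_negative={n_neg}, n_positive={n_pos})"
            )

    merged = pd.concat(rows)
    merged = merged.set_index(merged["variant_id"].astype(str)).loc[ids]
    return TrainingSet(
        gene=gene,
        variant_ids=ids,
        X=merged[cols].to_numpy(dtype=float),
        y=merged["y"].to_numpy(dtype=float),
        predictor_names=cols,
        n_negative=n_neg,
        n_positive=n_pos,
        borrow_log=borrow_log,
    )


# ---------------------------------------------------------------------------
# stepwise selection


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _irls_logit(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, max_iter: int = 40, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Ridge-stabilised IRLS logistic fit; returns (beta, log-likelihood)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = X.T @ (X * w[:, None])
        A[np.diag_indices(p)] += ridge
        new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -30.0, 30.0)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, ll


def _stepwise(X: np.ndarray, y: np.ndarray, penalty: float, ll_cache: dict) -> list[int]:
    """Bidirectional stepwise minimisation of -2*loglik + penalty*(K+1)."""
    n_pred = X.shape[1]

    def loglik(subset: tuple[int, ...]) -> float:
        if subset not in ll_cache:
            Xd = _add_intercept(X[:, list(subset)]) if subset else np.ones((X.shape[0], 1))
            _, ll = _irls_logit(Xd, y)
            ll_cache[subset] = ll
        return ll_cache[subset]

    def crit(subset: tuple[int, ...]) -> float:
        return -2.0 * loglik(subset) + penalty * (len(subset) + 1)

    current: tuple[int, ...] = ()
    current_crit = crit(current)
    while True:
        best_move, best_crit = None, current_crit - 1e-9
        for j in range(n_pred):
            if j in current:
                continue
            cand = tuple(sorted(current + (j,)))
            val = crit(cand)
            if val < best_crit:
                best_move, best_crit = cand, val
        for j in current:
            cand = tuple(k for k in current if k != j)
            val = crit(cand)
            if val < best_crit:
                best_move, best_crit = cand, val
        if best_move is None:
            break
        current, current_crit = best_move, best_crit
    return list(current)


def _cv_error(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int], folds: int, seed: int
) -> float:
    """Stratified k-fold misclassification rate of the subset at threshold 0.5."""
    n_splits = int(min(folds, (y == 1).sum(), (y == 0).sum()))
    if n_splits < 2:
        # too few of one class to cross validate; fall back to training error
        Xd = _add_intercept(X[:, list(subset)]) if subset else np.ones((len(y), 1))
        beta, _ = _irls_logit(Xd, y)
        pred = expit(Xd @ beta) >= 0.5
        return float(np.mean(pred != (y == 1)))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    errors = 0
    for train_idx, test_idx in skf.split(X, y):
        Xtr = _add_intercept(X[np.ix_(train_idx, list(subset))]) if subset else np.ones((len(train_idx), 1))
        Xte = _add_intercept(X[np.ix_(test_idx, list(subset))]) if subset else np.ones((len(test_idx), 1))
        beta, _ = _irls_logit(Xtr, y[train_idx])
        pred = expit(Xte @ beta) >= 0.5
        errors += int(np.sum(pred != (y[test_idx] == 1)))
    return errors / len(y)


def select_predictors(
    training: TrainingSet,
    penalties: Sequence[float] = (2, 3, 4, 5, 6, 7, 8),
    cv_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Predictor subset with minimal cross-validated error over the penalty sweep.

    For each penalty coefficient a bidirectional stepwise search minimises
    ``-2 loglik + penalty * (K+1)``; the resulting subsets are scored by
    stratified CV misclassification and the best one wins (ties broken by
    smaller subset size, then lower penalty).  An empty stepwise result
    falls back to the single predictor with the lowest CV error.
    """
    X, y = training.X, training.y
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training responses are all identical")
    ll_cache: dict = {}
    candidates: list[tuple[float, int, float, tuple[int, ...]]] = []
    cv_cache: dict[tuple[int, ...], float] = {}

    def cv_err(subset: tuple[int, ...]) -> float:
        if subset not in cv_cache:
            cv_cache[subset] = _cv_error(X, y, subset, cv_folds, seed)
        return cv_cache[subset]

    for penalty in penalties:
        subset = tuple(_stepwise(X, y, float(penalty), ll_cache))
        if not subset:
            singles = [(cv_err((j,)), j) for j in range(X.shape[1])]
            subset = (min(singles)[1],)
        candidates.append((cv_err(subset), len(subset), float(penalty), subset))
    best = min(candidates)
    return [training.predictor_names[j] for j in best[3]]


# ---------------------------------------------------------------------------
# Pólya-Gamma Gibbs sampling


def fit_pg_logistic(
    training: TrainingSet,
    predictors: Sequence[str],
    n_samples: int = 1000,
    burn_in: int = 20000,
    prior_var: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> IVPModel:
    """Bayesian logistic regression via the Pólya-Gamma Gibbs sampler.

    Coefficients carry independent Normal(0, prior_var) priors.  The chain
    runs ``burn_in`` iterations then retains ``n_samples`` consecutive joint
    draws (no thinning).  Deterministic given the seed.
    """
    idx = [training.predictor_names.index(p) for p in predictors]
    X = _add_intercept(training.X[:, idx])
    y = training.y
    if len(np.unique(y)) < 2:
        raise SamplerError("response is all-one or all-zero; cannot fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = X.shape
    prior_prec = 1.0 / float(prior_var)
    kappa_x = X.T @ (y - 0.5)
    beta = np.zeros(p)
    samples = np.empty((n_samples, p))
    for it in range(burn_in + n_samples):
        omega = draw_pg1(X @ beta, rng)
        prec = X.T @ (X * omega[:, None])
        prec[np.diag_indices(p)] += prior_prec
        L = np.linalg.cholesky(prec)
        mean = solve_triangular(
            L.T, solve_triangular(L, kappa_x, lower=True), lower=False
        )
        beta = mean + solve_triangular(L.T, rng.standard_normal(p), lower=False)
        if it >= burn_in:
            samples[it - burn_in] = beta
    if not np.all(np.isfinite(samples)):
        raise SamplerError("Pólya-Gamma sampler produced non-finite coefficients")
    return IVPModel(
        gene=training.gene,
        predictors=list(predictors),
        coef_samples=samples,
        settings={
            "n_samples": n_samples,
            "burn_in": burn_in,
            "prior_var": prior_var,
            "n_train": n,
        },
        borrow_log=list(training.borrow_log),
    )


def predict_distribution(model: IVPModel, scores: pd.Series | dict) -> ProbabilityDistribution:
    """IVP probability distribution for one variant from its scaled scores."""
    x = []
    for name in model.predictors:
        try:
            val = scores[name]
        except KeyError:
            raise InvalidInputError(f"missing predictor value for {name!r}") from None
        if val is None or not np.isfinite(val):
            raise InvalidInputError(
                f"predictor {name!r} is missing; impute scores before prediction"
            )
        x.append(float(val))
    eta = model.coef_samples[:, 0] + model.coef_samples[:, 1:] @ np.asarray(x)
    return ProbabilityDistribution(samples=expit(eta), role="ivp")
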