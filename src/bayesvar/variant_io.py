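"""Variant table I/O: consensus classes, unit scaling and kNN imputation.

A variant table is a pandas DataFrame with one row per variant carrying at
least ``variant_id``, ``gene`` and either a ``consensus_class`` column (one
of benign/VLB/VUS/VLP/pathogenic/excluded) or per-submitter count columns
(``n_positive``/``n_negative``/``n_vus``) from which the consensus is
derived.  Score columns hold the in silico predictor values, raw or already
unit-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError

NEGATIVE_CLASSES = ("benign", "VLB")
POSITIVE_CLASSES = ("VLP", "pathogenic")
CLASS_LABELS = ("benign", "VLB", "VUS", "VLP", "pathogenic")

#: default (x_min, x_max) per predictor.  Predictors already on the unit
#: scale map through (0, 1); SIFT is direction-flipped via x_min > x_max.
DEFAULT_SCALING: Mapping[str, tuple[float, float]] = {
    "Grantham": (5.0, 220.0),
    "GERP++": (-12.3, 6.2),
    "phastCons_vertebrate": (0.0, 1.0),
    "phastCons_mammalian": (0.0, 1.0),
    "AGVGD": (0.0, 65.0),
    "SIFT": (1.0, 0.0),
    "MutPred": (0.0, 1.0),
    "SiPhy": (0.0, 38.0),
    "LRT": (0.0, 1.0),
    "phyloP_vertebrate": (-20.0, 10.0),
    "phyloP_mammalian": (-13.3, 1.2),
    "Polyphen2_HVAR": (0.0, 1.0),
    "Polyphen2_HDIV": (0.0, 1.0),
    "MutationAssessor": (-5.2, 6.5),
    "PROVEAN": (-14.0, 14.0),
    "FATHMM": (-16.2, 10.7),
}

STANDALONE_PREDICTORS = tuple(DEFAULT_SCALING)


@dataclass(frozen=True)
class SubmitterLabels:
    """Counts of submitters asserting positive / negative / VUS for one variant."""

    variant_id: str
    n_positive: int
    n_negative: int
    n_vus: int

    def __post_init__(self) -> None:
        for name in ("n_positive", "n_negative", "n_vus"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.n_positive + self.n_negative + self.n_vus == 0:
            raise InvalidInputError(
                f"variant {self.variant_id!r}: at least one submitter count must be > 0"
            )


def derive_consensus_class(labels: SubmitterLabels) -> str:
    """Derive the consensus class ('positive', 'negative' or 'excluded').

    Majority rules first; a tie with VUS and no opposing class keeps the
    asserted class; conflicting positive/negative counts or unanimous VUS
    exclude the variant.
    """
    n_pos, n_neg, n_vus = labels.n_positive, labels.n_negative, labels.n_vus
    if n_pos > max(n_neg, n_vus):
        return "positive"
    if n_neg > max(n_pos, n_vus):
        return "negative"
    if n_pos == n_vus and n_neg == 0 and n_pos > 0:
        return "positive"
    if n_neg == n_vus and n_pos == 0 and n_neg > 0:
        return "negative"
    return "excluded"


def response_from_class(consensus_class) -> float:
    """Binary response: 1 for pathogenic/VLP, 0 for benign/VLB, NaN otherwise."""
    if consensus_class in POSITIVE_CLASSES:
        return 1.0
    if consensus_class in NEGATIVE_CLASSES:
        return 0.0
    return np.nan


@dataclass
class ScoreScalingSpec:
    """Affine unit-scaling constants per predictor.

    Each predictor maps through ``(x - x_min) / (x_max - x_min)``; raw values
    outside the [min, max] range are clamped to the boundary first, so scaled
    output always lies in [0, 1].  ``x_min > x_max`` flips direction (used
    for scores where low raw values indicate pathogenicity).
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALING)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo == hi:
                raise ConfigError(f"scaling for {name!r}: x_min == x_max")

    def scale(self, name: str, raw):
        if name not in self.bounds:
            raise ConfigError(f"no scaling constants for predictor {name!r}")
        lo, hi = self.bounds[name]
        raw = np.asarray(raw, dtype=float)
        clamped = np.clip(raw, min(lo, hi), max(lo, hi))
        return (clamped - lo) / (hi - lo)

    def unscale(self, name: str, scaled):
        if name not in self.bounds:
            raise ConfigError(f"no scaling constants for predictor {name!r}")
        lo, hi = self.bounds[name]
        return np.asarray(scaled, dtype=float) * (hi - lo) + lo

    @classmethod
    def identity(cls, columns: Iterable[str]) -> "ScoreScalingSpec":
        return cls(bounds={c: (0.0, 1.0) for c in columns})


def unit_scale_scores(raw: pd.DataFrame, spec: ScoreScalingSpec) -> pd.DataFrame:
    """Unit-scale every column of ``raw`` using ``spec``; NaNs pass through."""
    out = {}
    for col in raw.columns:
        out[col] = spec.scale(col, raw[col].to_numpy(dtype=float))
    return pd.DataFrame(out, index=raw.index)


def _masked_distances(block: np.ndarray, full: np.ndarray) -> np.ndarray:
    """Pairwise distances between rows of ``block`` and ``full`` with missing cells.

    Distance is the Euclidean distance over the predictors observed in both
    rows, rescaled by the fraction of predictors shared so that rows with
    different missingness patterns are comparable:
    ``d = sqrt(sum_shared (xi - xj)^2 / frac_shared)``.  No shared predictor
    gives an infinite distance.
    """
    p = full.shape[1]
    bm = np.isfinite(block)
    fm = np.isfinite(full)
    b0 = np.where(bm, block, 0.0)
    f0 = np.where(fm, full, 0.0)
    # sum over shared cells of (xi - xj)^2, expanded to avoid a 3-D temp
    shared = bm.astype(float) @ fm.T.astype(float)  # (nb, nf) counts
    sq = (
        (b0**2) @ fm.T.astype(float)
        + bm.astype(float) @ (f0**2).T
        - 2.0 * b0 @ f0.T
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = sq * (p / shared)
    d2[shared == 0] = np.inf
    return np.sqrt(np.maximum(d2, 0.0))


def impute_missing_knn(scores: pd.DataFrame, k: int = 40) -> pd.DataFrame:
    """Fill missing score cells with the mean of the k nearest neighbours.

    Neighbour distances and imputed means are computed from the original
    (pre-imputation) matrix only, so the operation is idempotent.  For a
    cell, only neighbours observing that predictor are eligible; if fewer
    than ``k`` exist all of them are used; if none exist an error names the
    predictor.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    X = scores.to_numpy(dtype=float)
    n, p = X.shape
    observed = np.isfinite(X)
    all_missing = ~observed.any(axis=0)
    if all_missing.any():
        bad = [scores.columns[j] for j in np.where(all_missing)[0]]
        raise InvalidInputError(f"predictor(s) missing for all variants: {bad}")
    if observed.all():
        return scores.copy()
    filled = X.copy()
    rows_missing = np.where(~observed.all(axis=1))[0]
    for i in rows_missing:
        d = _masked_distances(X[i : i + 1], X)[0]
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        for j in np.where(~observed[i])[0]:
            donors = order[observed[order, j] & np.isfinite(d[order])]
            if donors.size == 0:
                raise InvalidInputError(
                    f"no neighbour observes predictor {scores.columns[j]!r} "
                    f"for row {scores.index[i]!r}"
                )
            filled[i, j] = float(np.mean(X[donors[:k], j]))
    return pd.DataFrame(filled, index=scores.index, columns=scores.columns)


def read_variant_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV/XLSX variant table, optionally renaming columns.

    ``column_map`` maps source column names to the canonical names used by
    the pipeline (variant_id, gene, residue, consensus_class, score names).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)  # needs openpyxl
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path, metadata: Mapping | None = None) -> None:
    """Write a variant table as CSV with optional ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def normalize_panel(
    df: pd.DataFrame,
    scaling: ScoreScalingSpec | None = None,
    score_columns: Iterable[str] | None = None,
    k: int = 40,
    per_gene: bool = False,
    assume_unit_scale: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalise a raw variant table for model fitting.

    Derives ``consensus_class`` from submitter counts when absent, the
    binary response ``y``, unit-scales the score columns and imputes missing
    cells (pooled across the panel by default, per gene with ``per_gene``).
    Returns the normalised table and the list of score columns.
    """
    df = df.copy()
    if "variant_id" not in df.columns or "gene" not in df.columns:
        raise InvalidInputError("variant table needs 'variant_id' and 'gene' columns")
    if "consensus_class" not in df.columns:
        needed = {"n_positive", "n_negative", "n_vus"}
        if not needed.issubset(df.columns):
            raise InvalidInputError(
                "variant table needs 'consensus_class' or submitter count columns "
                f"{sorted(needed)}"
            )
        df["consensus_class"] = [
            derive_consensus_class(
                SubmitterLabels(str(r.variant_id), int(r.n_positive), int(r.n_negative), int(r.n_vus))
            )
            for r in df.itertuples(index=False)
        ]
    df["y"] = df["consensus_class"].map(response_from_class)

    if score_columns is None:
        score_cols = [c for c in df.columns if c in DEFAULT_SCALING]
        if not score_cols:
            reserved = {
                "variant_id", "gene", "residue", "consensus_class", "y",
                "n_positive", "n_negative", "n_vus",
            }
            score_cols = [
                c for c in df.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
            ]
    else:
        score_cols = list(score_columns)
    if not score_cols:
        raise InvalidInputError("no score columns found in variant table")

    if scaling is None:
        bounds = {}
        for c in score_cols:
            if c in DEFAULT_SCALING:
                bounds[c] = DEFAULT_SCALING[c]
            elif assume_unit_scale:
                bounds[c] = (0.0, 1.0)
            else:
                raise ConfigError(f"no scaling constants for predictor {c!r}")
        scaling = ScoreScalingSpec(bounds=bounds)

    df[score_cols] = unit_scale_scores(df[score_cols], scaling)
    if per_gene:
        parts = []
        for _, sub in df.groupby("gene", sort=False):
            parts.append(impute_missing_knn(sub[score_cols], k=k))
        imputed = pd.concat(parts).loc[df.index]
    else:
        imputed = impute_missing_knn(df[score_cols], k=k)
    df[score_cols] = imputed
    return df, score_cols
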