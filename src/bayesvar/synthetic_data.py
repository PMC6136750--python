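"""Synthetic multigene variant panels for testing every pipeline stage.

Panels mimic the structure the framework expects: several genes of varying
size, class-conditional unit-scale scores (Beta-distributed, so bounds hold
by construction), optional missingness, and sparse qualitative evidence
whose direction follows the true class.  Ground truth goes to a sidecar
record that the pipeline never reads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evidence_lr import CATEGORIES

SCORE_COLUMNS = tuple(f"s{i:02d}" for i in range(1, 17))

_PATHOGENIC_LEVELS = (("P-1", 0.45), ("LP-1", 0.3), ("P-4", 0.15), ("LP-4", 0.1))
_BENIGN_LEVELS = (("B-1", 0.25), ("LB-1", 0.45), ("LB-2", 0.3))


@dataclass
class SimulationConfig:
    n_genes: int = 10
    gene_sizes: Sequence[int] | None = None  # drawn from size_range when None
    size_range: tuple[int, int] = (20, 80)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "benign": 0.25, "VLB": 0.20, "VUS": 0.10, "VLP": 0.20, "pathogenic": 0.25,
        }
    )
    n_informative: int = 3
    shift: float = 0.30  # informative-score mean shift from 0.5, per class side
    concentration: float = 12.0  # Beta concentration of informative scores
    noise_concentration: float = 4.0
    missing_rate: float = 0.0
    evidence_rate: float = 0.5  # per-category availability
    evidence_consistency: float = 0.95  # P(direction matches truth)
    residue_pool: int = 150  # residues drawn per gene; small pool -> hotspots
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.gene_sizes is not None:
            if len(self.gene_sizes) != self.n_genes:
                raise ConfigError("gene_sizes length must equal n_genes")
            if any(s < 1 for s in self.gene_sizes):
                raise ConfigError("gene sizes must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - {"benign", "VLB", "VUS", "VLP", "pathogenic"}
        if unknown:
            raise ConfigError(f"unknown classes in proportions: {sorted(unknown)}")
        for name in ("missing_rate", "evidence_rate", "evidence_consistency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (1 <= self.n_informative <= len(SCORE_COLUMNS)):
            raise ConfigError("n_informative must be between 1 and 16")
        if not (0.0 < self.shift <= 0.5):
            raise ConfigError("shift must be in (0, 0.5]")


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-3), 1.0 - 1e-3)
    return mean * conc, (1.0 - mean) * conc


def simulate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a variant panel and its ground-truth record.

    Returns a table in the normalised input dialect (``variant_id``,
    ``gene``, ``residue``, ``consensus_class`` and 16 unit-scale score
    columns, NaN where missing) plus a dict with the per-gene informative
    predictors and per-variant truth, deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i + 1:02d}" for i in range(config.n_genes)]
    if config.gene_sizes is not None:
        sizes = list(config.gene_sizes)
    else:
        lo, hi = config.size_range
        sizes = rng.integers(lo, hi + 1, size=config.n_genes).tolist()

    class_names = list(config.class_proportions)
    class_probs = np.array([config.class_proportions[c] for c in class_names])
    truth_genes: dict[str, dict] = {}
    rows = []
    for gene, size in zip(genes, sizes):
        informative = sorted(
            rng.choice(len(SCORE_COLUMNS), size=config.n_informative, replace=False).tolist()
        )
        truth_genes[gene] = {
            "informative": [SCORE_COLUMNS[j] for j in informative],
            "shift": config.shift,
        }
        classes = rng.choice(class_names, size=size, p=class_probs)
        residues = rng.integers(1, config.residue_pool + 1, size=size)
        for i in range(size):
            cls = str(classes[i])
            if cls in ("VLP", "pathogenic"):
                mean = 0.5 + config.shift
            elif cls in ("benign", "VLB"):
                mean = 0.5 - config.shift
            else:
                mean = 0.5
            scores = np.empty(len(SCORE_COLUMNS))
            for j in range(len(SCORE_COLUMNS)):
                if j in informative:
                    a, b = _beta_params(mean, config.concentration)
                else:
                    a, b = _beta_params(0.5, config.noise_concentration)
                scores[j] = rng.beta(a, b)
            if config.missing_rate > 0:
                mask = rng.random(len(SCORE_COLUMNS)) < config.missing_rate
                scores[mask] = np.nan
            rows.append(
                {
                    "variant_id": f"{gene}:v{i + 1:04d}",
                    "gene": gene,
                    "residue": int(residues[i]),
                    "consensus_class": cls,
                    **{SCORE_COLUMNS[j]: scores[j] for j in range(len(SCORE_COLUMNS))},
                }
            )
    panel = pd.DataFrame(rows)
    truth = {
        "seed": config.seed,
        "genes": truth_genes,
        "y_true": {
            r["variant_id"]: (
                1 if r["consensus_class"] in ("VLP", "pathogenic")
                else 0 if r["consensus_class"] in ("benign", "VLB")
                else None
            )
            for r in rows
        },
    }
    return panel, truth


def simulate_evidence(panel: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Long-format qualitative evidence table aligned with true classes.

    Each of the 7 categories is available with ``evidence_rate``; available
    items carry a level code drawn from the truth-consistent pool with
    probability ``evidence_consistency``, otherwise from the opposite pool.
    VUS-truth variants get evidence at half the rate with random direction.
    Uses a dedicated RNG stream derived from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    def _draw(pool) -> str:
        codes = [c for c, _ in pool]
        probs = np.array([p for _, p in pool])
        return str(rng.choice(codes, p=probs / probs.sum()))

    rows = []
    for row in panel.itertuples(index=False):
        cls = row.consensus_class
        if cls in ("VLP", "pathogenic"):
            y = 1
        elif cls in ("benign", "VLB"):
            y = 0
        else:
            y = None
        for cat in CATEGORIES:
            rate = config.evidence_rate if y is not None else config.evidence_rate * 0.5
            if rng.random() >= rate:
                continue
            if y is None:
                toward_pathogenic = bool(rng.random() < 0.5)
            else:
                consistent = rng.random() < config.evidence_consistency
                toward_pathogenic = bool(y) if consistent else not bool(y)
            pool = _PATHOGENIC_LEVELS if toward_pathogenic else _BENIGN_LEVELS
            rows.append(
                {
                    "variant_id": row.variant_id,
                    "category": cat,
                    "level_code": _draw(pool),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "category", "level_code"])


def write_truth(truth: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth, indent=1))


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["class_proportions"] = dict(config.class_proportions)
    return d
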