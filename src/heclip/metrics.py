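"""Evaluation of imputed expression against ground truth.

All metrics operate on spots x genes matrices and are computed per gene
across spots (RMSE, SSIM, PCC) or per spot (Hit@T):

- RMSE_i  = sqrt( mean_j (pred_ij - truth_ij)^2 )
- SSIM_i  = (2*mu~_i*mu_i + C1)(2*cov_i + C2) /
            ((mu~_i^2 + mu_i^2 + C1)(sd~_i^2 + sd_i^2 + C2)),
  computed after each gene column is scaled by its own maximum, with
  population (1/M) moments and small stabilizers C1, C2.
- PCC_i   = Pearson correlation of the two columns.
- Hit@T   = fraction of spots whose top predicted gene is among the T
  highest truly expressed genes of that spot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MetricConfig:
    C1: float = 0.01
    C2: float = 0.01
    hit_T_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    scale_pred_by_truth_max: bool = False

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")


@dataclass
class MetricsReport:
    rmse: np.ndarray
    ssim: np.ndarray
    pcc: np.ndarray
    hit_at: dict[int, float]
    config: MetricConfig = field(default_factory=MetricConfig)

    @property
    def summaries(self) -> dict[str, float]:
        return {
            "rmse_median": float(np.median(self.rmse)),
            "rmse_mean": float(np.mean(self.rmse)),
            "ssim_median": float(np.median(self.ssim)),
            "ssim_mean": float(np.mean(self.ssim)),
            "pcc_median": float(np.median(self.pcc)),
            "pcc_mean": float(np.mean(self.pcc)),
        }

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse.tolist(),
            "ssim": self.ssim.tolist(),
            "pcc": self.pcc.tolist(),
            "hit_at": {str(t): v for t, v in self.hit_at.items()},
            "summaries": self.summaries,
            "config": {"C1": self.config.C1, "C2": self.config.C2,
                       "hit_T_values": list(self.config.hit_T_values),
                       "scale_pred_by_truth_max": self.config.scale_pred_by_truth_max},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(text: str) -> "MetricsReport":
        d = json.loads(text)
        cfg = d.get("config", {})
        cfg["hit_T_values"] = tuple(cfg.get("hit_T_values", (1, 2, 3, 4, 5)))
        return MetricsReport(
            rmse=np.asarray(d["rmse"], dtype=np.float64),
            ssim=np.asarray(d["ssim"], dtype=np.float64),
            pcc=np.asarray(d["pcc"], dtype=np.float64),
            hit_at={int(t): v for t, v in d["hit_at"].items()},
            config=MetricConfig(**cfg),
        )


def _check_shapes(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.ndim != 2 or truth.shape != pred.shape:
        raise ValueError(f"truth {truth.shape} and pred {pred.shape} must be equal 2-D shapes")
    return truth, pred


def rmse_per_gene(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    truth, pred = _check_shapes(truth, pred)
    if truth.shape[0] < 1:
        raise ValueError("need at least one spot")
    return np.sqrt(np.mean((pred - truth) ** 2, axis=0))


def scale_expression(matrix: np.ndarray) -> np.ndarray:
    """Divide each gene column by its own maximum (all-zero columns stay 0)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if np.any(matrix < 0):
        raise ValueError("scale_expression expects non-negative entries")
    col_max = matrix.max(axis=0)
    zero = col_max == 0
    if np.any(zero):
        logger.warning("%d all-zero gene column(s) left unscaled", int(zero.sum()))
    safe = np.where(zero, 1.0, col_max)
    return matrix / safe


def ssim_per_gene(
    truth_scaled: np.ndarray, pred_scaled: np.ndarray, config: MetricConfig | None = None
) -> np.ndarray:
    config = config or MetricConfig()
    truth_scaled, pred_scaled = _check_shapes(truth_scaled, pred_scaled)
    m = truth_scaled.shape[0]
    if m < 2:
        raise ValueError("SSIM needs at least 2 spots")
    mu_t = truth_scaled.mean(axis=0)
    mu_p = pred_scaled.mean(axis=0)
    var_t = truth_scaled.var(axis=0)  # population moments: no Bessel correction
    var_p = pred_scaled.var(axis=0)
    cov = ((truth_scaled - mu_t) * (pred_scaled - mu_p)).mean(axis=0)
    c1, c2 = config.C1, config.C2
    return ((2 * mu_p * mu_t + c1) * (2 * cov + c2)) / (
        (mu_p**2 + mu_t**2 + c1) * (var_p + var_t + c2)
    )


def pcc_per_gene(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Per-gene Pearson correlation across spots; constant columns give 0."""
    truth, pred = _check_shapes(truth, pred)
    if truth.shape[0] < 2:
        raise ValueError("PCC needs at least 2 spots")
    t = truth - truth.mean(axis=0)
    p = pred - pred.mean(axis=0)
    st = np.sqrt((t**2).sum(axis=0))
    sp = np.sqrt((p**2).sum(axis=0))
    degenerate = (st == 0) | (sp == 0)
    if np.any(degenerate):
        logger.warning("%d zero-variance gene column(s); PCC set to 0", int(degenerate.sum()))
    denom = np.where(degenerate, 1.0, st * sp)
    out = (t * p).sum(axis=0) / denom
    out[degenerate] = 0.0
    return out


def _truth_top_t(truth: np.ndarray, t: int) -> np.ndarray:
    # stable sort on negated values: rank ties go to the lower gene index
    return np.argsort(-truth, axis=1, kind="stable")[:, :t]


def hit_at_t(truth: np.ndarray, pred: np.ndarray, T: int) -> float:
    """Fraction of spots whose top predicted gene is among the spot's T
    highest truly expressed genes."""
    truth, pred = _check_shapes(truth, pred)
    d = truth.shape[1]
    if not 1 <= T <= d:
        raise ValueError(f"T must lie in [1, {d}], got {T}")
    pred_top = pred.argmax(axis=1)
    truth_top = _truth_top_t(truth, T)
    hits = (truth_top == pred_top[:, None]).any(axis=1)
    return float(hits.mean())


def summarize(
    truth: np.ndarray, pred: np.ndarray, config: MetricConfig | None = None
) -> MetricsReport:
    """Compute the full report: per-gene RMSE/SSIM/PCC and Hit@T rates."""
    config = config or MetricConfig()
    truth, pred = _check_shapes(truth, pred)
    truth_s = scale_expression(np.clip(truth, 0.0, None))
    pred_nonneg = np.clip(pred, 0.0, None)
    if config.scale_pred_by_truth_max:
        col_max = np.clip(truth, 0.0, None).max(axis=0)
        pred_s = pred_nonneg / np.where(col_max == 0, 1.0, col_max)
    else:
        pred_s = scale_expression(pred_nonneg)
    return MetricsReport(
        rmse=rmse_per_gene(truth, pred),
        ssim=ssim_per_gene(truth_s, pred_s, config),
        pcc=pcc_per_gene(truth, pred),
        hit_at={t: hit_at_t(truth, pred, t) for t in config.hit_T_values},
        config=config,
    )
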