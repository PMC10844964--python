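"""Marker-intensity thresholding and hi/lo cell classification.

Thresholds are derived from the shape of the per-marker intensity
distribution: the default model is a two-component Gaussian mixture on
log10 intensities whose equal-posterior crossing separates the lo and hi
populations.  ``hi`` is always a strict inequality (intensity > threshold),
so a threshold of exactly 0 splits "no expression" from "any expression".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .io_tables import CellRecord

__all__ = [
    "ThresholdMethod",
    "ThresholdFit",
    "SubsetDefinition",
    "CheckpointStatus",
    "CD68_CD163_LABELS",
    "fit_marker_threshold",
    "classify_cd68_cd163",
    "classify_checkpoint",
]

LOG_EPS = 1.0  # intensity offset before log10, admits zero intensities


class ThresholdMethod(str, enum.Enum):
    GAUSSIAN_MIXTURE_2 = "GAUSSIAN_MIXTURE_2"
    MEAN_PLUS_K_SD = "MEAN_PLUS_K_SD"
    FIXED = "FIXED"


class CheckpointStatus(str, enum.Enum):
    HI = "HI"
    LO = "LO"


@dataclass(frozen=True)
class ThresholdFit:
    """A fitted hi/lo intensity threshold for one marker."""

    marker: str
    threshold: float
    method: ThresholdMethod
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "threshold": self.threshold,
            "method": self.method.value,
            "diagnostics": dict(self.diagnostics),
        }


CD68_CD163_LABELS = (
    "CD68hiCD163lo",
    "CD68hiCD163hi",
    "CD68loCD163hi",
    "CD68loCD163lo",
)


@dataclass(frozen=True)
class SubsetDefinition:
    """Per-marker thresholds plus the hi/lo-vector -> label rule."""

    marker_thresholds: Mapping[str, float]

    def is_hi(self, cell: CellRecord, marker: str) -> bool:
        if marker not in cell.intensities:
            raise KeyError(f"cell {cell.cell_id}: missing marker {marker!r}")
        return cell.intensities[marker] > self.marker_thresholds[marker]


def _log10p(values: np.ndarray) -> np.ndarray:
    return np.log10(values + LOG_EPS)


def _mean_plus_k_sd(logs: np.ndarray, k: float) -> float:
    return float(10 ** (logs.mean() + k * logs.std(ddof=1)) - LOG_EPS)


def _mixture_crossing(
    w: np.ndarray, mu: np.ndarray, sd: np.ndarray
) -> float:
    """Equal-posterior crossing of a 2-component 1-D Gaussian mixture.

    Root of w0*N(x; mu0, sd0) = w1*N(x; mu1, sd1) between the two means.
    """
    lo, hi = sorted(mu)

    def diff(x: float) -> float:
        return w[0] * norm.pdf(x, mu[0], sd[0]) - w[1] * norm.pdf(x, mu[1], sd[1])

    if diff(lo) * diff(hi) > 0:  # no sign change between means (rare, skewed weights)
        grid = np.linspace(lo, hi, 512)
        vals = np.array([diff(g) for g in grid])
        sign_change = np.nonzero(np.diff(np.sign(vals)))[0]
        if len(sign_change) == 0:
            return float((lo + hi) / 2.0)
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    return float(brentq(diff, lo, hi))


def fit_marker_threshold(
    intensities: Sequence[float],
    method: ThresholdMethod = ThresholdMethod.GAUSSIAN_MIXTURE_2,
    params: Mapping[str, float] | None = None,
    marker: str = "",
) -> ThresholdFit:
    """Fit a hi/lo threshold to one marker's per-cell intensities.

    GAUSSIAN_MIXTURE_2 fits two Gaussians to log10(intensity + 1) and
    returns the equal-posterior crossing back-transformed to intensity
    units; if the fitted components are separated by less than
    ``params["min_sep"]`` pooled SDs (default 0.5) it falls back to
    MEAN_PLUS_K_SD and records the fallback in the diagnostics.
    MEAN_PLUS_K_SD returns mean + k*SD on log scale (default k=2).
    FIXED returns ``params["value"]`` unchanged.
    """
    params = dict(params or {})
    if method is ThresholdMethod.FIXED:
        if "value" not in params:
            raise ValueError("FIXED method requires params['value']")
        return ThresholdFit(marker, float(params["value"]), ThresholdMethod.FIXED)

    values = np.asarray(list(intensities), dtype=float)
    if values.size == 0:
        raise ValueError("no intensity values")
    if np.ptp(values) == 0:
        raise ValueError("all intensity values are equal; threshold undefined")
    logs = _log10p(values)

    if method is ThresholdMethod.MEAN_PLUS_K_SD:
        k = float(params.get("k", 2.0))
        thr = _mean_plus_k_sd(logs, k)
        return ThresholdFit(
            marker,
            thr,
            ThresholdMethod.MEAN_PLUS_K_SD,
            {"log_mean": float(logs.mean()), "log_sd": float(logs.std(ddof=1)), "k": k},
        )

    if method is ThresholdMethod.GAUSSIAN_MIXTURE_2:
        if values.size < 50:
            raise ValueError(
                f"mixture method needs >= 50 values, got {values.size}"
            )
        min_sep = float(params.get("min_sep", 0.5))
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            random_state=int(params.get("random_state", 0)),
            n_init=int(params.get("n_init", 3)),
        )
        gm.fit(logs.reshape(-1, 1))
        gm1 = GaussianMixture(
            n_components=1,
            covariance_type="full",
            random_state=int(params.get("random_state", 0)),
        ).fit(logs.reshape(-1, 1))
        bic2 = float(gm.bic(logs.reshape(-1, 1)))
        bic1 = float(gm1.bic(logs.reshape(-1, 1)))
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.ravel())
        w = gm.weights_.ravel()
        order = np.argsort(mu)
        mu, sd, w = mu[order], sd[order], w[order]
        pooled_sd = float(np.sqrt(np.mean(sd**2)))
        separation = float(abs(mu[1] - mu[0]) / pooled_sd)
        diagnostics = {
            "log_mean_lo": float(mu[0]),
            "log_mean_hi": float(mu[1]),
            "log_sd_lo": float(sd[0]),
            "log_sd_hi": float(sd[1]),
            "weight_lo": float(w[0]),
            "weight_hi": float(w[1]),
            "separation_sd": separation,
            "bic_1": bic1,
            "bic_2": bic2,
        }
        # degenerate when the components barely separate or a single
        # Gaussian explains the data at least as well (BIC)
        if separation < min_sep or bic1 <= bic2:
            k = float(params.get("k", 2.0))
            thr = _mean_plus_k_sd(logs, k)
            diagnostics["fallback"] = 1.0
            diagnostics["k"] = k
            return ThresholdFit(marker, thr, ThresholdMethod.MEAN_PLUS_K_SD, diagnostics)
        log_thr = _mixture_crossing(w, mu, sd)
        thr = float(10**log_thr - LOG_EPS)
        thr = float(np.clip(thr, values.min(), values.max()))
        return ThresholdFit(marker, thr, ThresholdMethod.GAUSSIAN_MIXTURE_2, diagnostics)

    raise ValueError(f"unknown threshold method: {method}")


def classify_cd68_cd163(cell: CellRecord, definition: SubsetDefinition) -> str:
    """Assign one of the four CD68/CD163 hi/lo subset labels.

    ``hi`` means strictly above the marker threshold; a value exactly at
    the threshold is ``lo``.
    """
    cd68_hi = definition.is_hi(cell, "CD68")
    cd163_hi = definition.is_hi(cell, "CD163")
    if cd68_hi and not cd163_hi:
        return "CD68hiCD163lo"
    if cd68_hi and cd163_hi:
        return "CD68hiCD163hi"
    if not cd68_hi and cd163_hi:
        return "CD68loCD163hi"
    return "CD68loCD163lo"


def classify_checkpoint(
    cell: CellRecord, marker: str, threshold: float
) -> CheckpointStatus:
    """HI iff the cell's marker intensity strictly exceeds ``threshold``.

    With ``threshold=0`` this separates zero expression from any positive
    expression level.
    """
    if marker not in cell.intensities:
        raise KeyError(f"cell {cell.cell_id}: missing marker {marker!r}")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (
        CheckpointStatus.HI
        if cell.intensities[marker] > threshold
        else CheckpointStatus.LO
    )
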