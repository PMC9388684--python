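"""Evaluation: pixel metrics, biomarker errors, error-spread model, Bland-Altman.

Pixel metrics (accuracy, DICE, modified Hausdorff distance) are computed on
probability maps binarized at 0.5.  Biomarker errors follow the 100%-error
rule: an absent estimate contributes 100% to the mean absolute percentage
error.  The error-spread model fits ``f(n) = a * exp(b * n) + c`` to the
binned mean and binned SD of the biomarker error as a function of the number
of detected cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

__all__ = [
    "segmentation_metrics",
    "parameter_errors",
    "fit_error_model",
    "bland_altman",
    "ErrorModel",
    "modified_hausdorff",
]

ABSENT = None  # marker for 'no estimate' entries in paired lists


def _foreground(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float) >= 0.5


def modified_hausdorff(a_points: np.ndarray, b_points: np.ndarray) -> float:
    """Modified Hausdorff distance between two point sets.

    MHD(A, B) = max( mean_a min_b d(a,b), mean_b min_a d(a,b) ) with
    Euclidean d.  Both sets must be non-empty.
    """
    a_points = np.atleast_2d(np.asarray(a_points, dtype=float))
    b_points = np.atleast_2d(np.asarray(b_points, dtype=float))
    if a_points.size == 0 or b_points.size == 0:
        raise ValueError("MHD is undefined for an empty point set")
    d_ab = cKDTree(b_points).query(a_points)[0].mean()
    d_ba = cKDTree(a_points).query(b_points)[0].mean()
    return float(max(d_ab, d_ba))


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Accuracy, DICE and MHD between two probability maps (threshold 0.5).

    Both maps empty: DICE = 1 and MHD = 0 by convention (logged).  Exactly
    one map empty: DICE = 0 and MHD raises, mirroring its undefinedness.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = _foreground(pred)
    b = _foreground(truth)
    accuracy = float((a == b).mean())
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("both foregrounds empty: DICE := 1, MHD := 0", stacklevel=2)
        return {"accuracy": accuracy, "dice": 1.0, "mhd": 0.0}
    inter = int((a & b).sum())
    dice = 2.0 * inter / (na + nb)
    if na == 0 or nb == 0:
        raise ValueError("MHD undefined: one foreground is empty")
    mhd = modified_hausdorff(np.argwhere(a), np.argwhere(b))
    return {"accuracy": accuracy, "dice": dice, "mhd": mhd}


def parameter_errors(estimates: list, truths: list) -> dict:
    """MAE and MAPE of paired biomarker estimates.

    ``estimates`` may contain ``None`` for absent estimates; these are
    skipped in the MAE and contribute 100% to the MAPE.  Pairs whose truth
    is <= 0 are excluded from the MAPE with a warning.
    """
    if len(estimates) != len(truths):
        raise ValueError("estimates and truths must be paired")
    abs_errors = []
    pct_errors = []
    for est, truth in zip(estimates, truths):
        if est is None:
            pct_errors.append(100.0)
            continue
        abs_errors.append(abs(est - truth))
        if truth <= 0:
            warnings.warn(f"non-positive truth {truth} excluded from MAPE", stacklevel=2)
            continue
        pct_errors.append(100.0 * abs(est - truth) / truth)
    mae = float(np.mean(abs_errors)) if abs_errors else None
    mape = float(np.mean(pct_errors)) if pct_errors else None
    return {"mae": mae, "mape": mape}


@dataclass(frozen=True)
class ErrorModel:
    """Exponential model f(n) = a * exp(b * n) + c of error mean and spread."""

    mean_params: tuple[float, float, float]
    sd_params: tuple[float, float, float]
    mean_r2: float
    sd_r2: float
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray

    def mean(self, n):
        a, b, c = self.mean_params
        return a * np.exp(b * np.asarray(n, dtype=float)) + c

    def sd(self, n):
        a, b, c = self.sd_params
        return a * np.exp(b * np.asarray(n, dtype=float)) + c


def _exp_model(n, a, b, c):
    return a * np.exp(b * n) + c


def _fit_exponential(x: np.ndarray, y: np.ndarray,
                     sigma: np.ndarray | None = None) -> tuple[tuple, float]:
    span = y[0] - y[-1] if len(y) > 1 else (y[0] if len(y) else 1.0)
    scale = max(x.max() - x.min(), 1.0)
    p0 = (span if span != 0 else 1.0, -1.0 / scale, y[-1] if len(y) else 0.0)
    try:
        popt, _ = curve_fit(_exp_model, x, y, p0=p0, sigma=sigma,
                            absolute_sigma=False, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    resid = y - _exp_model(x, *popt)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return tuple(popt), float(r2)


def fit_error_model(errors, n_cells, bin_width: int = 10) -> ErrorModel:
    """Fit exponentials to the binned mean and SD of the error vs cell count.

    Errors are binned by ``n_cells`` with the given bin width; bins with
    fewer than 3 points are dropped; at least 3 usable bins are required.
    """
    errors = np.asarray(errors, dtype=float)
    n_cells = np.asarray(n_cells, dtype=float)
    if errors.shape != n_cells.shape:
        raise ValueError("errors and n_cells must be paired")
    bins = np.floor(n_cells / bin_width).astype(int)
    centers, means, sds, counts = [], [], [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 3:
            continue
        centers.append((b + 0.5) * bin_width)
        means.append(errors[sel].mean())
        sds.append(errors[sel].std(ddof=1))
        counts.append(int(sel.sum()))
    if len(centers) < 3:
        raise ValueError(f"need >= 3 bins with >= 3 points, got {len(centers)}")
    centers = np.array(centers)
    means = np.array(means)
    sds = np.array(sds)
    counts = np.array(counts, dtype=float)
    # weighted least squares: the standard error of a binned mean is
    # SD/sqrt(n), of a binned sample SD about SD/sqrt(2(n-1))
    mean_sigma = np.maximum(sds, 1e-12) / np.sqrt(counts)
    sd_sigma = np.maximum(sds, 1e-12) / np.sqrt(2.0 * (counts - 1.0))
    mean_params, mean_r2 = _fit_exponential(centers, means, mean_sigma)
    sd_params, sd_r2 = _fit_exponential(centers, sds, sd_sigma)
    return ErrorModel(mean_params, sd_params, mean_r2, sd_r2, centers, means, sds)


def bland_altman(estimates, truths) -> dict:
    """Bland-Altman agreement: bias, 95% limits, % of differences within them."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must be paired")
    if len(estimates) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = estimates - truths
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(100.0 * ((d >= loa_low) & (d <= loa_high)).mean())
    return {"bias": bias, "loa_low": loa_low, "loa_high": loa_high, "pct_within": within}
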