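"""Sensitized-emission FRET correction and quantification.

The raw FRET image (acceptor emission under donor excitation, I_DA) mixes
three components: true energy transfer, donor emission bleeding into the
acceptor detection band (proportional to I_DD), and direct excitation of the
acceptor by the donor laser line (proportional to I_AA).  Single-label
control samples give the two mixing coefficients, and the corrected stack is

    Fc = I_DA - d * I_DD - a * I_AA

computed in signed arithmetic.  The "any FRET signal" readout is the
percentage of pixels inside the donor∩acceptor mask with positive corrected
signal, and per-case means are compared to zero with a one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FretCoefficients",
    "FretResult",
    "estimate_crosstalk",
    "estimate_direct_excitation",
    "correct_fret",
    "fret_positive_fraction",
    "one_sample_t",
]


@dataclass(frozen=True)
class FretCoefficients:
    """Bleed-through (d) and direct-excitation (a) coefficients."""

    d: float
    a: float
    n_pixels_d: int = 0
    n_pixels_a: int = 0
    residual_scale_d: float = 0.0
    residual_scale_a: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d", "a"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"coefficient {name} must be finite and >= 0, got {v}")


@dataclass
class FretResult:
    """Corrected stack and the percent of overlap-mask pixels with signal."""

    corrected: np.ndarray
    percent_positive: float
    n_overlap_pixels: int
    coefficients: FretCoefficients


def _origin_slope(x: np.ndarray, y: np.ndarray, threshold: float) -> tuple[float, int, float]:
    """Least-squares slope through the origin of y on x over x > threshold."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("control stacks must share shape")
    sel = x > threshold
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no above-threshold pixels in control sample")
    xs, ys = x[sel], y[sel]
    denom = float(np.dot(xs, xs))
    if denom == 0:
        raise ValueError("control reference channel has zero energy")
    slope = float(np.dot(xs, ys) / denom)
    resid = float(np.sqrt(np.mean((ys - slope * xs) ** 2)))
    return max(slope, 0.0), n, resid


def estimate_crosstalk(i_dd: np.ndarray, i_da: np.ndarray, threshold: float = 0.0) -> FretCoefficients:
    """Donor bleed-through ``d`` from a donor-only control (slope of I_DA on I_DD).

    Pixels with I_DD above ``threshold`` enter a least-squares fit through
    the origin; a single global slope per control sample is robust at low
    intensities.  The estimate is scale-invariant: multiplying both channels
    by a constant leaves it unchanged.
    """
    d, n, resid = _origin_slope(i_dd, i_da, threshold)
    return FretCoefficients(d=d, a=0.0, n_pixels_d=n, residual_scale_d=resid)


def estimate_direct_excitation(i_aa: np.ndarray, i_da: np.ndarray, threshold: float = 0.0) -> FretCoefficients:
    """Acceptor direct-excitation ``a`` from an acceptor-only control."""
    a, n, resid = _origin_slope(i_aa, i_da, threshold)
    return FretCoefficients(d=0.0, a=a, n_pixels_a=n, residual_scale_a=resid)


def estimate_coefficients(
    donor_only: dict[str, np.ndarray],
    acceptor_only: dict[str, np.ndarray],
    threshold: float = 0.0,
) -> FretCoefficients:
    """Both coefficients from their control samples (keys I_DD, I_DA, I_AA)."""
    cd = estimate_crosstalk(donor_only["I_DD"], donor_only["I_DA"], threshold)
    ca = estimate_direct_excitation(acceptor_only["I_AA"], acceptor_only["I_DA"], threshold)
    return FretCoefficients(
        d=cd.d, a=ca.a,
        n_pixels_d=cd.n_pixels_d, n_pixels_a=ca.n_pixels_a,
        residual_scale_d=cd.residual_scale_d, residual_scale_a=ca.residual_scale_a,
    )


def correct_fret(
    i_da: np.ndarray, i_dd: np.ndarray, i_aa: np.ndarray, coeffs: FretCoefficients
) -> np.ndarray:
    """Linear unmixing: ``Fc = I_DA - d*I_DD - a*I_AA`` (negatives preserved)."""
    i_da = np.asarray(i_da, dtype=float)
    i_dd = np.asarray(i_dd, dtype=float)
    i_aa = np.asarray(i_aa, dtype=float)
    if not (i_da.shape == i_dd.shape == i_aa.shape):
        raise ValueError(
            f"stack shapes differ: {i_da.shape}, {i_dd.shape}, {i_aa.shape}"
        )
    return i_da - coeffs.d * i_dd - coeffs.a * i_aa


def fret_positive_fraction(
    corrected: np.ndarray,
    donor_mask: np.ndarray,
    acceptor_mask: np.ndarray,
    positivity_bound: float = 0.0,
) -> float:
    """Percent of donor∩acceptor pixels with corrected signal above the bound.

    The default bound of 0 counts "any FRET signal"; a noise floor (e.g. a
    percentile of Fc outside the masks) can be supplied instead.  An empty
    overlap mask yields NaN with a warning — a missing value, not 0.
    """
    donor_mask = np.asarray(donor_mask, dtype=bool)
    acceptor_mask = np.asarray(acceptor_mask, dtype=bool)
    if donor_mask.shape != corrected.shape or acceptor_mask.shape != corrected.shape:
        raise ValueError("masks must match the corrected stack shape")
    overlap = donor_mask & acceptor_mask
    n = int(overlap.sum())
    if n == 0:
        warnings.warn("fret_positive_fraction: empty donor∩acceptor overlap; undefined")
        return float("nan")
    return 100.0 * int((np.asarray(corrected)[overlap] > positivity_bound).sum()) / n


def one_sample_t(
    case_means: Sequence[float], mu: float = 0.0, n_comparisons: int = 1
) -> tuple[float, int, float, float]:
    """One-sample t-test of per-case means against ``mu``.

    Returns ``(t, df, p, p_bonferroni)`` with the two-sided p multiplied by
    ``n_comparisons`` and capped at 1.  Cases are biological replicates:
    exactly one mean per case enters.
    """
    x = np.asarray(list(case_means), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 case means")
    if np.ptp(x) == 0:
        raise ValueError("zero variance across case means")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    res = stats.ttest_1samp(x, popmean=mu)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = int(x.size - 1)
    return t, df, p, min(1.0, p * n_comparisons)
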