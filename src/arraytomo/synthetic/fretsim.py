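"""Synthetic control sets for sensitized-emission FRET.

Builds the three sample types a FRET experiment acquires: a donor-only
control (acceptor-channel signal is pure bleed-through, ``I_DA = d *
I_DD``), an acceptor-only control (``I_DA = a * I_AA``), and a double-label
sample whose FRET image mixes both confounds with a known true FRET
component inside the signal mask.  In noise-free mode the mixtures are exact
linear identities, so the correction's recovery can be checked to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FretSample", "generate_fret_set"]


@dataclass
class FretSample:
    """One acquired sample: the three detection channels plus the truth."""

    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    f_true: np.ndarray


def _smooth_positive(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    """A smooth non-negative intensity field emulating stained structures."""
    field = rng.random(shape)
    field = ndimage.gaussian_filter(field, sigma=2.0)
    field -= field.min()
    peak = field.max()
    if peak > 0:
        field /= peak
    return scale * field


def generate_fret_set(
    d_true: float,
    a_true: float,
    signal_mask: np.ndarray,
    seed: int = 0,
    shape: tuple[int, ...] | None = None,
    f_true: np.ndarray | float = 50.0,
    noise_sd: float = 0.0,
    scale: float = 200.0,
) -> dict[str, FretSample]:
    """Generate ``{donor_only, acceptor_only, double_label}`` sample triples.

    ``signal_mask`` bounds the true FRET component of the double-label
    sample; ``f_true`` may be a scalar amplitude (applied inside the mask)
    or a full array.  ``noise_sd`` adds Gaussian noise to every channel
    (0 = exact construction).
    """
    if d_true < 0 or a_true < 0:
        raise ValueError(f"coefficients must be >= 0, got d={d_true}, a={a_true}")
    signal_mask = np.asarray(signal_mask, dtype=bool)
    shape = shape or signal_mask.shape
    if signal_mask.shape != shape:
        raise ValueError("signal_mask shape must match the requested shape")
    rng = np.random.default_rng(seed)

    if np.isscalar(f_true):
        f_arr = np.where(signal_mask, float(f_true), 0.0)
    else:
        f_arr = np.asarray(f_true, dtype=float) * signal_mask
    if np.any(f_arr != 0) and not signal_mask.any():
        raise ValueError("signal_mask is empty but a FRET component was requested")

    def _noisy(x: np.ndarray) -> np.ndarray:
        return x + rng.normal(0.0, noise_sd, x.shape) if noise_sd > 0 else x

    dd = _smooth_positive(rng, shape, scale)
    donor_only = FretSample(
        i_dd=_noisy(dd), i_da=_noisy(d_true * dd),
        i_aa=np.zeros(shape), f_true=np.zeros(shape),
    )

    aa = _smooth_positive(rng, shape, scale)
    acceptor_only = FretSample(
        i_dd=np.zeros(shape), i_da=_noisy(a_true * aa),
        i_aa=_noisy(aa), f_true=np.zeros(shape),
    )

    dd2 = _smooth_positive(rng, shape, scale) + scale * 0.25 * signal_mask
    aa2 = _smooth_positive(rng, shape, scale) + scale * 0.25 * signal_mask
    double = FretSample(
        i_dd=_noisy(dd2),
        i_da=_noisy(d_true * dd2 + a_true * aa2 + f_arr),
        i_aa=_noisy(aa2),
        f_true=f_arr,
    )
    return {"donor_only": donor_only, "acceptor_only": acceptor_only, "double_label": double}
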