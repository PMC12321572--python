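"""Imaging model: rasterize a scene and apply acquisition confounds.

Each physical section is the analytic slice of every ellipsoidal punctum at
that z, at a constant per-punctum amplitude.  Confounds, all optional and
individually seeded: per-section rigid misalignment (recorded in the truth
exactly as applied; the first section anchors the frame), Gaussian PSF blur,
Poisson photon noise followed by additive Gaussian read noise, and bright
single-section speckles emulating secondary-antibody precipitate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ..registration import RigidTransform, apply_rigid
from ..stacks import MultiChannelStack
from .scene import DEFAULT_CHANNEL_MAP, SceneTruth, _seed_streams

__all__ = ["OpticsParams", "render_stacks"]

#: amplitude of an ideal punctum, in detector counts
PUNCTUM_AMPLITUDE = 200.0


@dataclass(frozen=True)
class OpticsParams:
    """Acquisition confounds applied to the ideal scene rendering."""

    psf_sigma_xy: float = 0.1        # um; 0 disables blur
    gaussian_noise_sd: float = 2.0   # counts; 0 disables read noise
    photon_noise: bool = True
    jitter_translation_max: float = 2.0   # px, per section, uniform
    jitter_rotation_max: float = 0.5      # degrees, per section, uniform
    speckle_rate: float = 0.0        # expected speckles per section per channel
    bit_depth: int | None = 16       # None: leave float, no quantization
    interp_order: int = 1            # 0 = nearest (exact for integer shifts)

    def __post_init__(self) -> None:
        if self.psf_sigma_xy < 0:
            raise ValueError(f"psf_sigma_xy must be >= 0, got {self.psf_sigma_xy}")
        if self.gaussian_noise_sd < 0:
            raise ValueError(f"gaussian_noise_sd must be >= 0, got {self.gaussian_noise_sd}")
        if self.jitter_translation_max < 0 or self.jitter_rotation_max < 0:
            raise ValueError("jitter bounds must be >= 0")
        if self.speckle_rate < 0:
            raise ValueError(f"speckle_rate must be >= 0, got {self.speckle_rate}")

    @classmethod
    def ideal(cls) -> "OpticsParams":
        """Identity optics: no blur, no noise, no jitter, no quantization."""
        return cls(
            psf_sigma_xy=0.0, gaussian_noise_sd=0.0, photon_noise=False,
            jitter_translation_max=0.0, jitter_rotation_max=0.0,
            speckle_rate=0.0, bit_depth=None,
        )


def _rasterize_puncta(truth: SceneTruth, role: str) -> np.ndarray:
    """Ideal stack for one role: analytic ellipsoid slices at amplitude."""
    p = truth.params
    g = p.geometry
    nz, ny, nx = p.grid_shape
    out = np.zeros((nz, ny, nx), dtype=float)
    df = truth.role(role)
    clipped_any = False
    for row in df.itertuples():
        j0 = max(int(np.floor((row.cx - row.rx) / g.dx)), 0)
        j1 = min(int(np.ceil((row.cx + row.rx) / g.dx)) + 1, nx)
        i0 = max(int(np.floor((row.cy - row.ry) / g.dy)), 0)
        i1 = min(int(np.ceil((row.cy + row.ry) / g.dy)) + 1, ny)
        k0 = max(int(np.floor((row.cz - row.rz) / g.dz)), 0)
        k1 = min(int(np.ceil((row.cz + row.rz) / g.dz)) + 1, nz)
        if j0 >= j1 or i0 >= i1 or k0 >= k1:
            clipped_any = True
            continue
        if row.clipped:
            clipped_any = True
        z = np.arange(k0, k1) * g.dz
        y = np.arange(i0, i1) * g.dy
        x = np.arange(j0, j1) * g.dx
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        inside = (
            ((xx - row.cx) / row.rx) ** 2
            + ((yy - row.cy) / row.ry) ** 2
            + ((zz - row.cz) / row.rz) ** 2
        ) <= 1.0
        out[k0:k1, i0:i1, j0:j1] += PUNCTUM_AMPLITUDE * inside
    if clipped_any:
        warnings.warn(f"{role}: one or more puncta clipped at the field border")
    return out


def render_stacks(
    truth: SceneTruth,
    optics: OpticsParams | None = None,
    channel_map: dict[str, str] | None = None,
) -> MultiChannelStack:
    """Render the multichannel serial-section stack for a scene.

    Per section: jitter (identical transform for every channel, recorded in
    ``truth.transforms``), PSF blur, Poisson photon noise, Gaussian read
    noise, speckles (recorded in ``truth.speckles``), then optional
    quantization.  Deterministic for fixed (truth, optics).
    """
    optics = optics or OpticsParams()
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    p = truth.params
    g = p.geometry
    nz, ny, nx = p.grid_shape

    ideal: dict[str, np.ndarray] = {}
    for role in ("pre", "post", "tau"):
        ideal[channel_map[role]] = _rasterize_puncta(truth, role)
    ideal[channel_map["astro"]] = truth.astro_mask.astype(float) * PUNCTUM_AMPLITUDE

    streams = _seed_streams(truth.seed)
    rng_jitter, rng_noise, rng_speckle = (
        streams["jitter"], streams["noise"], streams["speckle"],
    )

    # --- per-section rigid jitter (section 0 anchors the frame) ---------
    tmax, rmax = optics.jitter_translation_max, optics.jitter_rotation_max
    rows = [{"section": 0, "dx": 0.0, "dy": 0.0, "theta": 0.0}]
    for s in range(1, nz):
        rows.append(
            {
                "section": s,
                "dx": float(rng_jitter.uniform(-tmax, tmax)) if tmax else 0.0,
                "dy": float(rng_jitter.uniform(-tmax, tmax)) if tmax else 0.0,
                "theta": float(rng_jitter.uniform(-rmax, rmax)) if rmax else 0.0,
            }
        )
    transforms = pd.DataFrame(rows)

    sigma_px = optics.psf_sigma_xy / g.dx
    channels: dict[str, np.ndarray] = {}
    speckle_rows: list[dict] = []
    speckle_id = 1
    for name, stack in ideal.items():
        out = np.empty_like(stack)
        for s in range(nz):
            img = stack[s]
            t = transforms.iloc[s]
            if t.dx or t.dy or t.theta:
                img = apply_rigid(
                    img, RigidTransform(dx=t.dx, dy=t.dy, theta=t.theta),
                    order=optics.interp_order,
                )
            if sigma_px > 0:
                img = ndimage.gaussian_filter(img, sigma=sigma_px)
            if optics.photon_noise:
                img = rng_noise.poisson(np.clip(img, 0, None)).astype(float)
            if optics.gaussian_noise_sd > 0:
                img = img + rng_noise.normal(0.0, optics.gaussian_noise_sd, img.shape)
            n_speck = rng_speckle.poisson(optics.speckle_rate) if optics.speckle_rate else 0
            for _ in range(n_speck):
                ci = rng_speckle.uniform(0, ny)
                cj = rng_speckle.uniform(0, nx)
                amp = PUNCTUM_AMPLITUDE * rng_speckle.uniform(0.6, 1.2)
                ii = np.arange(max(int(ci) - 4, 0), min(int(ci) + 5, ny))
                jj = np.arange(max(int(cj) - 4, 0), min(int(cj) + 5, nx))
                yy, xx = np.meshgrid(ii, jj, indexing="ij")
                img[yy, xx] += amp * np.exp(
                    -(((yy - ci) ** 2 + (xx - cj) ** 2) / (2 * 1.2**2))
                )
                speckle_rows.append(
                    {"id": speckle_id, "channel": name, "section": s,
                     "x_um": cj * g.dx, "y_um": ci * g.dy}
                )
                speckle_id += 1
            out[s] = np.clip(img, 0.0, None)
        if optics.bit_depth is not None:
            out = np.clip(np.round(out), 0, 2**optics.bit_depth - 1)
        channels[name] = out

    truth.transforms = transforms
    truth.speckles = pd.DataFrame(
        speckle_rows, columns=["id", "channel", "section", "x_um", "y_um"]
    )
    return MultiChannelStack(channels=channels, geometry=g, aligned=False)
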