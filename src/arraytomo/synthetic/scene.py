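"""Ground-truthed synthetic array tomography scenes.

The generator reproduces the statistical structure the downstream analyses
assume: presynaptic puncta scattered as a Poisson process, a configurable
fraction of them given a postsynaptic partner at a sub-0.5 um centroid
offset, tau assigned to presynapses at rate ``p_pre`` and to paired
postsynapses conditionally on the partner (``q1`` when the partner carries
tau, ``q0`` otherwise), plus an astrocyte arbor mask engulfing a chosen
fraction of puncta.  Every random element is driven by named substreams of a
single seed, so geometry is unchanged when only noise settings change and
regeneration is bit-identical.

Identifiability by construction: a paired postsynapse is placed so that its
true partner is also its *nearest* presynapse, and orphan postsynapses are
placed with no presynapse within the pairing radius.  Ground truth is then
exactly what a correct nearest-neighbour pairing at the 0.5 um criterion
should recover; robustness to imaging confounds is probed separately via
the optics model.  Tau puncta are likewise placed fully inside their host
(or, in partial mode, at a programmed overlap fraction) so truth at the
25%-overlap colocalization criterion is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from ..segmentation import ObjectTable
from ..stacks import VoxelGeometry

__all__ = ["SceneParams", "SceneTruth", "generate_scene", "objects_from_truth"]

#: default mapping from generative role to fluorescence channel label
DEFAULT_CHANNEL_MAP = {"pre": "SYO", "post": "PSD95", "tau": "T22", "astro": "GFAP"}

#: pairing radius (um) under which ground-truth pairs must be identifiable
PAIRING_RADIUS = 0.5


@dataclass(frozen=True)
class SceneParams:
    """Geometry and statistical structure of one synthetic scene.

    Lengths in micrometres, densities in puncta per um^3, probabilities in
    [0, 1].  ``punctum_radii`` are per-axis ellipsoid semi-axes (x, y, z).
    ``tau_scale`` sets tau punctum semi-axes relative to the host;
    ``tau_overlap_fraction=None`` places tau fully inside its host, a value
    in (0, 1] programs a partial volume overlap to probe the colocalization
    threshold boundary.
    """

    field_x: float = 50.0
    field_y: float = 50.0
    n_sections: int = 20
    section_thickness: float = 0.07
    pixel_size: float = 0.1
    pre_density: float = 0.5
    paired_fraction: float = 0.8
    pair_offset_range: tuple[float, float] = (0.1, 0.45)
    orphan_post_density: float = 0.05
    punctum_radii: tuple[float, float, float] = (0.3, 0.3, 0.2)
    tau_scale: float = 0.7
    tau_overlap_fraction: float | None = None
    p_pre: float = 0.3
    q1: float = 0.6
    q0: float = 0.02
    astro_fraction_of_volume: float = 0.1
    engulf_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("field_x", "field_y", "section_thickness", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SceneParams.{name} must be > 0, got {getattr(self, name)}")
        if self.n_sections < 1:
            raise ValueError(f"SceneParams.n_sections must be >= 1, got {self.n_sections}")
        for name in ("pre_density", "orphan_post_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"SceneParams.{name} must be >= 0, got {getattr(self, name)}")
        for name in ("paired_fraction", "p_pre", "q1", "q0",
                     "astro_fraction_of_volume", "engulf_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"SceneParams.{name} must be in [0, 1], got {v}")
        lo, hi = self.pair_offset_range
        if not 0 < lo <= hi:
            raise ValueError(f"SceneParams.pair_offset_range must satisfy 0 < min <= max, got {self.pair_offset_range}")
        if hi > PAIRING_RADIUS:
            raise ValueError(
                f"SceneParams.pair_offset_range max must be <= {PAIRING_RADIUS} um "
                f"(pairs must be detectable), got {hi}"
            )
        if any(r <= 0 for r in self.punctum_radii):
            raise ValueError(f"SceneParams.punctum_radii must be > 0, got {self.punctum_radii}")
        if not 0 < self.tau_scale < 1:
            raise ValueError(f"SceneParams.tau_scale must be in (0, 1), got {self.tau_scale}")
        if self.tau_overlap_fraction is not None and not 0 < self.tau_overlap_fraction <= 1:
            raise ValueError(
                f"SceneParams.tau_overlap_fraction must be in (0, 1], got {self.tau_overlap_fraction}"
            )
        if self.engulf_fraction > 0 and self.astro_fraction_of_volume == 0:
            raise ValueError(
                "SceneParams.engulf_fraction > 0 requires astro_fraction_of_volume > 0"
            )

    @property
    def depth(self) -> float:
        return self.n_sections * self.section_thickness

    @property
    def volume(self) -> float:
        return self.field_x * self.field_y * self.depth

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(dx=self.pixel_size, dy=self.pixel_size, dz=self.section_thickness)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return (
            self.n_sections,
            int(round(self.field_y / self.pixel_size)),
            int(round(self.field_x / self.pixel_size)),
        )

    @property
    def implied_true_enrichment(self) -> float:
        """Closed-form enrichment ratio the generator targets:
        q1 / (p_pre*q1 + (1-p_pre)*q0)."""
        base = self.p_pre * self.q1 + (1.0 - self.p_pre) * self.q0
        return self.q1 / base if base > 0 else float("nan")


@dataclass
class SceneTruth:
    """Everything the generator knows about one scene.

    ``puncta`` columns: ``id, role, cx, cy, cz, rx, ry, rz, tau, engulfed,
    host_id, clipped`` (roles: pre, post, tau).  ``pairing`` columns:
    ``post_id, pre_id, offset_um``.  ``transforms`` (``section, dx, dy,
    theta``) and ``speckles`` (``id, channel, section, x_um, y_um``) are
    recorded by the renderer exactly as applied.  ``astro_mask`` is the
    boolean astrocyte arbor on the voxel grid.
    """

    params: SceneParams
    puncta: pd.DataFrame
    pairing: pd.DataFrame
    astro_mask: np.ndarray
    implied_true_enrichment: float
    seed: int
    transforms: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["section", "dx", "dy", "theta"])
    )
    speckles: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "channel", "section", "x_um", "y_um"])
    )

    def role(self, role: str) -> pd.DataFrame:
        return self.puncta[self.puncta["role"] == role]


def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named substreams of one seed: changing the optics (noise) model never
    perturbs geometry or flags."""
    kids = np.random.SeedSequence(seed).spawn(6)
    names = ["placement", "flags", "astro", "jitter", "noise", "speckle"]
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def _place_paired_posts(
    rng: np.random.Generator,
    pre_xyz: np.ndarray,
    paired_idx: np.ndarray,
    params: SceneParams,
    max_rounds: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place posts at offsets from their partner pre, guaranteeing the
    partner is the post's nearest pre.  Returns (post_xyz, kept partner
    indices, offsets)."""
    tree = cKDTree(pre_xyz)
    lo, hi = params.pair_offset_range
    bounds = np.array([params.field_x, params.field_y, params.depth])
    pending = paired_idx.copy()
    placed_xyz = np.zeros((len(paired_idx), 3))
    placed_off = np.zeros(len(paired_idx))
    placed_ok = np.zeros(len(paired_idx), dtype=bool)
    slot = {int(i): k for k, i in enumerate(paired_idx)}
    for _ in range(max_rounds):
        if len(pending) == 0:
            break
        r = rng.uniform(lo, hi, size=len(pending))
        cand = pre_xyz[pending] + _isotropic_directions(rng, len(pending)) * r[:, None]
        in_field = np.all((cand >= 0) & (cand < bounds), axis=1)
        _, nearest = tree.query(cand, k=1)
        ok = in_field & (nearest == pending)
        for j in np.nonzero(ok)[0]:
            k = slot[int(pending[j])]
            placed_xyz[k] = cand[j]
            placed_off[k] = r[j]
            placed_ok[k] = True
        pending = pending[~ok]
    return placed_xyz[placed_ok], paired_idx[placed_ok], placed_off[placed_ok]


def _place_orphan_posts(
    rng: np.random.Generator, pre_xyz: np.ndarray, n: int, params: SceneParams,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform posts with no pre within the pairing radius (true orphans)."""
    if n == 0:
        return np.zeros((0, 3))
    tree = cKDTree(pre_xyz) if len(pre_xyz) else None
    bounds = np.array([params.field_x, params.field_y, params.depth])
    out: list[np.ndarray] = []
    need = n
    for _ in range(max_rounds):
        if need <= 0:
            break
        cand = rng.uniform(0.0, 1.0, size=(need * 2 + 8, 3)) * bounds
        if tree is not None:
            d, _ = tree.query(cand, k=1)
            cand = cand[d > PAIRING_RADIUS]
        take = cand[:need]
        out.append(take)
        need -= len(take)
    return np.concatenate(out, axis=0) if out else np.zeros((0, 3))


def _tau_ellipsoid_samples(n_per_axis: int = 21) -> np.ndarray:
    """Deterministic unit-ball sample grid used for overlap integration."""
    g = np.linspace(-1, 1, n_per_axis)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    return pts[np.sum(pts**2, axis=1) <= 1.0]


def _overlap_fraction(offset: np.ndarray, host_r: np.ndarray, tau_r: np.ndarray,
                      samples: np.ndarray) -> float:
    """Fraction of the tau ellipsoid (centre ``offset`` from host centre)
    lying inside the host ellipsoid, by deterministic integration."""
    pts = samples * tau_r + offset
    inside = np.sum((pts / host_r) ** 2, axis=1) <= 1.0
    return float(inside.mean())


def _tau_offset_partial(
    direction: np.ndarray, host_r: np.ndarray, tau_r: np.ndarray, target: float,
    samples: np.ndarray,
) -> np.ndarray:
    """Bisection for the offset distance giving the programmed overlap."""
    lo_t, hi_t = 0.0, float(np.max(host_r + tau_r)) * 1.5
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        f = _overlap_fraction(direction * mid, host_r, tau_r, samples)
        if f > target:
            lo_t = mid
        else:
            hi_t = mid
    return direction * 0.5 * (lo_t + hi_t)


def generate_scene(params: SceneParams) -> SceneTruth:
    """Draw one complete ground-truthed scene from its parameters.

    The presynapse count is Poisson(pre_density x volume); paired posts get
    centroid offsets uniform in ``pair_offset_range`` with isotropic
    direction; tau flags follow (p_pre, q1, q0); each tau-positive punctum
    hosts one tau punctum.  Deterministic for fixed params.
    """
    streams = _seed_streams(params.seed)
    rng_place, rng_flags, rng_astro = (
        streams["placement"], streams["flags"], streams["astro"],
    )
    bounds = np.array([params.field_x, params.field_y, params.depth])

    n_pre = int(rng_place.poisson(params.pre_density * params.volume))
    pre_xyz = rng_place.uniform(0.0, 1.0, size=(n_pre, 3)) * bounds

    paired_mask = rng_place.random(n_pre) < params.paired_fraction
    paired_idx = np.nonzero(paired_mask)[0]
    if len(paired_idx) and n_pre:
        post_xyz, partner_idx, offsets = _place_paired_posts(
            rng_place, pre_xyz, paired_idx, params
        )
    else:
        post_xyz = np.zeros((0, 3))
        partner_idx = np.zeros(0, dtype=int)
        offsets = np.zeros(0)

    n_orphan = int(rng_place.poisson(params.orphan_post_density * params.volume))
    orphan_xyz = _place_orphan_posts(rng_place, pre_xyz, n_orphan, params)

    # --- tau flags ------------------------------------------------------
    pre_tau = rng_flags.random(n_pre) < params.p_pre
    partner_tau = pre_tau[partner_idx] if len(partner_idx) else np.zeros(0, dtype=bool)
    p_post = np.where(partner_tau, params.q1, params.q0)
    paired_post_tau = rng_flags.random(len(post_xyz)) < p_post
    orphan_post_tau = rng_flags.random(len(orphan_xyz)) < params.q0

    # --- assemble puncta table -----------------------------------------
    rx, ry, rz = params.punctum_radii
    pre_ids = np.arange(1, n_pre + 1)
    post_all_xyz = np.concatenate([post_xyz, orphan_xyz], axis=0)
    post_tau = np.concatenate([paired_post_tau, orphan_post_tau])
    post_ids = np.arange(n_pre + 1, n_pre + 1 + len(post_all_xyz))

    def _block(ids, xyz, role, tau, host=None):
        n = len(ids)
        return pd.DataFrame(
            {
                "id": ids,
                "role": role,
                "cx": xyz[:, 0], "cy": xyz[:, 1], "cz": xyz[:, 2],
                "rx": np.full(n, rx), "ry": np.full(n, ry), "rz": np.full(n, rz),
                "tau": np.asarray(tau, dtype=bool),
                "engulfed": np.zeros(n, dtype=bool),
                "host_id": np.full(n, -1, dtype=int) if host is None else host,
                "clipped": np.zeros(n, dtype=bool),
            }
        )

    pre_df = _block(pre_ids, pre_xyz.reshape(-1, 3), "pre", pre_tau)
    post_df = _block(post_ids, post_all_xyz.reshape(-1, 3), "post", post_tau)

    # --- tau puncta inside (or programmed-overlap with) their hosts -----
    hosts = pd.concat([pre_df[pre_df["tau"]], post_df[post_df["tau"]]])
    tau_rows = []
    next_id = n_pre + 1 + len(post_all_xyz)
    host_r = np.array([rx, ry, rz])
    tau_r = host_r * params.tau_scale
    samples = _tau_ellipsoid_samples() if params.tau_overlap_fraction is not None else None
    for _, h in hosts.iterrows():
        centre = np.array([h.cx, h.cy, h.cz])
        direction = _isotropic_directions(rng_flags, 1)[0]
        if params.tau_overlap_fraction is None:
            # containment of similar axis-aligned ellipsoids: scaled offset
            # norm <= 1 - tau_scale keeps tau fully inside the host
            u = rng_flags.random() ** (1.0 / 3.0)
            offset = direction * u * (1.0 - params.tau_scale) * host_r
        else:
            offset = _tau_offset_partial(
                direction, host_r, tau_r, params.tau_overlap_fraction, samples
            )
        c = centre + offset
        tau_rows.append(
            {
                "id": next_id, "role": "tau",
                "cx": c[0], "cy": c[1], "cz": c[2],
                "rx": tau_r[0], "ry": tau_r[1], "rz": tau_r[2],
                "tau": True, "engulfed": False, "host_id": int(h.id),
                "clipped": False,
            }
        )
        next_id += 1
    tau_df = pd.DataFrame(tau_rows, columns=pre_df.columns)
    if tau_df.empty:
        tau_df = tau_df.astype(pre_df.dtypes.to_dict())

    puncta = pd.concat([pre_df, post_df, tau_df], ignore_index=True)
    # clipped: any part of the ellipsoid outside the field
    r_arr = puncta[["rx", "ry", "rz"]].to_numpy()
    c_arr = puncta[["cx", "cy", "cz"]].to_numpy()
    puncta["clipped"] = np.any((c_arr - r_arr < 0) | (c_arr + r_arr > bounds), axis=1)

    pairing = pd.DataFrame(
        {
            "post_id": post_ids[: len(post_xyz)],
            "pre_id": pre_ids[partner_idx] if len(partner_idx) else np.zeros(0, dtype=int),
            "offset_um": offsets,
        }
    )

    # --- astrocyte arbor and engulfment ---------------------------------
    astro_mask, engulfed_ids = _astro_arbor(rng_astro, params, puncta)
    puncta["engulfed"] = puncta["id"].isin(engulfed_ids)

    return SceneTruth(
        params=params,
        puncta=puncta,
        pairing=pairing,
        astro_mask=astro_mask,
        implied_true_enrichment=params.implied_true_enrichment,
        seed=params.seed,
    )


def _astro_arbor(
    rng: np.random.Generator, params: SceneParams, puncta: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed random-walk filaments dilated to the target volume fraction.

    Walks are seeded at the centroids of the puncta selected for engulfment
    (so their centroids end up inside the mask without moving any synapse)
    plus extra random seeds, then the union is dilated until the target
    fraction is reached; the final dilation shell is subsampled to land on
    the target.
    """
    shape = params.grid_shape
    if params.astro_fraction_of_volume <= 0:
        return np.zeros(shape, dtype=bool), np.zeros(0, dtype=int)

    synaptic = puncta[puncta["role"].isin(["pre", "post"])]
    n_engulf = int(round(params.engulf_fraction * len(synaptic)))
    engulfed_ids = (
        rng.choice(synaptic["id"].to_numpy(), size=n_engulf, replace=False)
        if n_engulf else np.zeros(0, dtype=int)
    )
    sel = synaptic.set_index("id").loc[engulfed_ids] if n_engulf else None

    mask = np.zeros(shape, dtype=bool)
    g = params.geometry
    bounds = np.array([params.depth, params.field_y, params.field_x])
    voxel = np.array([g.dz, g.dy, g.dx])

    seeds_um: list[tuple[np.ndarray, int]] = []
    if sel is not None:
        # short walks through each engulfed punctum keep its centroid inside
        seeds_um += [(np.array([r.cz, r.cy, r.cx]), 60) for r in sel.itertuples()]
    n_extra = max(3, int(0.002 * params.volume))
    for _ in range(n_extra):
        seeds_um.append((rng.uniform(0, 1, size=3) * bounds, 400))

    for seed_pos, n_steps in seeds_um:
        # direction-correlated filament: Gaussian steps smoothed along the path
        steps = rng.normal(size=(n_steps, 3))
        steps = ndimage.gaussian_filter1d(steps, sigma=3.0, axis=0, mode="nearest")
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        steps = steps / np.maximum(norms, 1e-9) * voxel
        path = seed_pos + np.concatenate([np.zeros((1, 3)), np.cumsum(steps, axis=0)])
        path = np.clip(path, 0.0, bounds)
        idx = np.rint(path / voxel).astype(int)
        idx = np.minimum(idx, np.array(shape) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    target = int(round(params.astro_fraction_of_volume * mask.size))
    structure = ndimage.generate_binary_structure(3, 1)
    while int(mask.sum()) < target:
        grown = ndimage.binary_dilation(mask, structure=structure)
        if int(grown.sum()) <= int(mask.sum()):
            break
        if int(grown.sum()) > target:
            shell = grown & ~mask
            shell_idx = np.flatnonzero(shell.ravel())
            need = target - int(mask.sum())
            take = rng.choice(shell_idx, size=need, replace=False)
            flat = mask.ravel()
            flat[take] = True
            mask = flat.reshape(shape)
            break
        mask = grown
    return mask, engulfed_ids


def objects_from_truth(
    truth: SceneTruth, role: str, tau_from_truth: bool = True
) -> ObjectTable:
    """An :class:`ObjectTable` built directly from ground-truth centroids.

    This is the idealized (perfect-segmentation) observation of a scene,
    used to validate the pairing and enrichment statistics independently of
    the imaging model.
    """
    df = truth.role(role)
    volumes = 4.0 / 3.0 * np.pi * (df["rx"] * df["ry"] * df["rz"]).to_numpy()
    table = ObjectTable.from_centroids(
        df[["cx", "cy", "cz"]].to_numpy(),
        channel=DEFAULT_CHANNEL_MAP.get(role, role),
        geometry=truth.params.geometry,
        analyzed_volume=truth.params.volume,
        volumes_um3=volumes,
        extra={"tau": df["tau"].to_numpy()} if tau_from_truth else None,
    )
    out = table.df
    out["id"] = df["id"].to_numpy()
    return table
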