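"""Multichannel serial-section stacks and their TIFF round-trip.

An array tomography acquisition is a ribbon of ultrathin physical sections
(70 nm by default), each imaged once per fluorescence channel.  In memory a
stack is one 3D array per channel, shaped ``(sections, rows, cols)``, plus the
physical voxel geometry needed to convert voxel counts and indices into
micrometres.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = ["VoxelGeometry", "MultiChannelStack", "read_stack", "write_stack"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel in micrometres.

    ``dx``/``dy`` are the lateral pixel pitch; ``dz`` is the physical section
    thickness (0.07 um for ultrathin array tomography ribbons).  Section index
    ``k`` maps to ``z = k * dz``; column ``j`` to ``x = j * dx``; row ``i`` to
    ``y = i * dy`` (coordinates at voxel centres, 0-based).
    """

    dx: float = 0.1
    dy: float = 0.1
    dz: float = 0.07

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelGeometry.{name} must be strictly positive, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.dx * self.dy * self.dz


@dataclass
class MultiChannelStack:
    """Per-channel 3D intensity arrays sharing one geometry.

    ``channels`` maps a channel label (e.g. ``"SYO"``, ``"PSD95"``, ``"T22"``,
    ``"AT8"``, ``"GFAP"``) to a float array of shape ``(n_sections, ny, nx)``.
    ``valid_mask`` marks voxels inside the registered field of view; voxels
    that left the frame during alignment are excluded from every analyzed
    volume downstream.
    """

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    aligned: bool = False
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiChannelStack requires at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"channels must be 3D (sections, rows, cols); got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"all channels must share one shape; got {shapes}")
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
        if self.valid_mask is not None and self.valid_mask.shape != first:
            raise ValueError("valid_mask shape must match channel shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_sections(self) -> int:
        return self.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def valid(self) -> np.ndarray:
        """Boolean mask of analyzable voxels (all true when never aligned)."""
        if self.valid_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid_mask

    @property
    def analyzed_volume(self) -> float:
        """Volume of the valid region in um^3."""
        return float(self.valid().sum()) * self.geometry.voxel_volume

    def copy(self) -> "MultiChannelStack":
        return MultiChannelStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            geometry=self.geometry,
            aligned=self.aligned,
            valid_mask=None if self.valid_mask is None else self.valid_mask.copy(),
        )


_SEQ_RE = re.compile(r"(\d+)(?=\D*$)")


def _sequence_key(path: Path) -> tuple:
    """Sort key using the trailing integer in the filename, if any."""
    m = _SEQ_RE.search(path.stem)
    return (0, int(m.group(1))) if m else (1, path.name)


def read_stack(
    paths: Mapping[str, Sequence[str | Path] | str | Path],
    geometry: VoxelGeometry | None = None,
) -> MultiChannelStack:
    """Assemble a multichannel stack from TIFF files.

    Parameters
    ----------
    paths
        Mapping from channel label to either one multi-page TIFF path or a
        sequence of single-section TIFF paths.  Single-section files are
        ordered by the trailing integer in their filename.
    geometry
        Physical voxel geometry; defaults to 0.1 x 0.1 x 0.07 um.

    Raises
    ------
    FileNotFoundError
        If a mapped channel file does not exist (the message names the channel).
    ValueError
        If channels disagree in shape or section count.
    """
    geometry = geometry or VoxelGeometry()
    channels: dict[str, np.ndarray] = {}
    for name, src in paths.items():
        if isinstance(src, (str, Path)):
            files = [Path(src)]
        else:
            files = sorted((Path(p) for p in src), key=_sequence_key)
        for f in files:
            if not f.exists():
                raise FileNotFoundError(f"channel {name!r}: file not found: {f}")
        pages = [tifffile.imread(str(f)) for f in files]
        arr = pages[0] if len(pages) == 1 and pages[0].ndim == 3 else np.stack(
            [p if p.ndim == 2 else p[0] for p in pages], axis=0
        )
        if arr.ndim == 2:
            arr = arr[None]
        channels[name] = np.asarray(arr)

    shapes = {n: a.shape for n, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channels disagree in shape/section count: {shapes}")
    return MultiChannelStack(channels=channels, geometry=geometry)


def write_stack(
    stack: MultiChannelStack,
    out_dir: str | Path,
    prefix: str = "stack",
    interleaved: bool = False,
) -> dict[str, Path]:
    """Write a stack as OME-TIFF, one file per channel (or one interleaved file).

    Returns the mapping channel -> written path (a single ``"__all__"`` entry
    in interleaved mode).  Intensities are written unmodified so a
    write/read round trip is bit-exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = stack.geometry
    meta = {"axes": "ZYX", "PhysicalSizeX": g.dx, "PhysicalSizeY": g.dy, "PhysicalSizeZ": g.dz}
    written: dict[str, Path] = {}
    if interleaved:
        arr = np.stack([stack.channels[c] for c in stack.channel_names], axis=1)
        p = out_dir / f"{prefix}.ome.tif"
        tifffile.imwrite(str(p), arr, photometric="minisblack", metadata={**meta, "axes": "ZCYX"})
        written["__all__"] = p
    else:
        for name in stack.channel_names:
            p = out_dir / f"{prefix}_{name}.ome.tif"
            tifffile.imwrite(str(p), stack.channels[name], photometric="minisblack", metadata=meta)
            written[name] = p
    return written
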