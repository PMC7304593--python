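"""Stack and trace I/O, path resampling, and arc-length intensity profiles.

This module is the substrate for bouton-weight computation: it reads 3D
fluorescence stacks (multi-page TIFF, one page per z-plane) and axon
centerline traces (SWC, as produced by e.g. Simple Neurite Tracer),
resamples traces to a uniform arc-length step, and extracts the
fluorescence intensity along the axon as a function of arc length.

Conventions
-----------
* World coordinates are in micrometres, with the centre of voxel
  ``(ix, iy, iz)`` at ``((ix + 0.5) * voxel_xy, (iy + 0.5) * voxel_xy,
  (iz + 0.5) * voxel_z)``.
* Voxel arrays are indexed ``(z, y, x)``.
* Default voxel geometry is 0.11 um/pixel laterally and 0.7 um per
  z-plane (typical high-resolution two-photon acquisition of layer-1
  axons).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import map_coordinates

DEFAULT_VOXEL_XY = 0.11  # um / pixel
DEFAULT_VOXEL_Z = 0.7    # um / plane

#: default arc-length resampling step (um); below the lateral pixel size so
#: the 0.7-um cross-session identity tolerance spans several samples
DEFAULT_STEP_UM = 0.1

#: default profile-extraction disc radius (um), ~3 lateral pixels
DEFAULT_EXTRACTION_RADIUS = 0.33


class FormatError(ValueError):
    """Raised for malformed input files (ragged TIFF pages, cyclic SWC...)."""


class EmptyProfileError(ValueError):
    """Raised when a trace lies entirely outside its stack."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxonPath:
    """An ordered 3D polyline along one unbranched axon segment.

    Parameters
    ----------
    points
        ``(n, 3)`` array of (x, y, z) positions in um, ordered along the
        axon. Consecutive points must be at most 1 um apart so arc length
        approximates the true cable length.
    """

    points: np.ndarray
    trace_id: str = "axon"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("points must be an (n>=2, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive points must be distinct")
        if np.any(seg > 1.0 + 1e-9):
            raise ValueError("consecutive point spacing must be <= 1 um")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per point (um); starts at 0, strictly increasing."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s) -> np.ndarray:
        """Linear interpolation of the polyline at arc-length coordinate(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        arc = self.arc_length
        return np.stack(
            [np.interp(s, arc, self.points[:, k]) for k in range(3)], axis=-1
        )


@dataclass
class SessionStack:
    """One session's 3D fluorescence stack with its voxel geometry."""

    voxels: np.ndarray  # (nz, ny, nx), nonnegative
    voxel_xy: float = DEFAULT_VOXEL_XY
    voxel_z: float = DEFAULT_VOXEL_Z
    session_day: int = 0

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxels = v

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class ResampledPath:
    """An axon path resampled at a uniform arc-length step."""

    samples: np.ndarray          # (m, 3) points, um
    step: float                  # realized step (um); divides total length
    source_trace_id: str = "axon"
    degenerate: bool = False     # requested step exceeded the trace length

    @property
    def s(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.step

    @property
    def total_length(self) -> float:
        return (self.samples.shape[0] - 1) * self.step


@dataclass
class IntensityProfile:
    """Fluorescence intensity along one traced axon in one session.

    ``intensity[i]`` is the stack intensity at arc-length coordinate
    ``s[i]``; samples outside the stack are NaN (masked).
    """

    s: np.ndarray
    intensity: np.ndarray
    session_day: int = 0
    extraction_radius: float = DEFAULT_EXTRACTION_RADIUS

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must have equal length")
        valid = self.intensity[np.isfinite(self.intensity)]
        if valid.size and np.any(valid < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.s[1] - self.s[0]) if self.s.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s": self.s, "intensity": self.intensity,
             "session_day": self.session_day}
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_stack(path, voxel_xy=None, voxel_z=None, session_day=None) -> SessionStack:
    """Read a z-series TIFF as a :class:`SessionStack`.

    Voxel sizes and the session day are taken from a YAML sidecar
    ``<stem>.yaml`` next to the TIFF when present, falling back to the
    keyword arguments and then to the defaults (0.11 / 0.7 um).
    """
    import tifffile

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # ragged pages, truncation...
        raise FormatError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a z-series TIFF, got shape {arr.shape}")

    meta = {}
    sidecar = os.path.splitext(str(path))[0] + ".yaml"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return SessionStack(
        voxels=np.asarray(arr, dtype=np.float32),
        voxel_xy=float(meta.get("voxel_xy", voxel_xy or DEFAULT_VOXEL_XY)),
        voxel_z=float(meta.get("voxel_z", voxel_z or DEFAULT_VOXEL_Z)),
        session_day=int(meta.get("session_day",
                                 session_day if session_day is not None else 0)),
    )


def _subdivide_segments(pts: np.ndarray, max_spacing: float = 1.0
                        ) -> np.ndarray:
    """Insert collinear points so consecutive spacing is <= max_spacing.

    SWC nodes can be arbitrarily far apart; subdividing preserves the
    polyline (and its arc length) exactly while satisfying the AxonPath
    spacing invariant.
    """
    out = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / max_spacing)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.array(out)


def read_swc(path) -> list[AxonPath]:
    """Read an SWC trace, splitting at branch points into unbranched paths.

    Returns one :class:`AxonPath` per unbranched segment (a single-element
    list for an unbranched file). Node order in the file is irrelevant; the
    polylines are determined by the parent topology. Coordinates are taken
    as world um.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    nodes: dict[int, tuple[np.ndarray, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise FormatError(f"short SWC line: {line!r}")
            nid, parent = int(parts[0]), int(parts[6])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            if nid in nodes:
                raise FormatError(f"duplicate SWC node id {nid}")
            nodes[nid] = (xyz, parent)
    if not nodes:
        raise FormatError("empty SWC file")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid, (_, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise FormatError(f"SWC node {nid} references missing parent {parent}")
            children[parent].append(nid)
    if not roots:
        raise FormatError("SWC file has no root node (cyclic parent links?)")

    # cycle check: every node must reach a root
    for nid in nodes:
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise FormatError("cyclic parent links in SWC file")
            seen.add(cur)
            cur = nodes[cur][1]

    # walk from each root / branch point to the next branch point or leaf
    stem = os.path.splitext(os.path.basename(str(path)))[0]
    paths: list[AxonPath] = []
    stack = [(r, [r]) for r in sorted(roots)]
    while stack:
        start, prefix = stack.pop(0)
        for child in sorted(children[start]):
            chain = list(prefix)
            cur = child
            while True:
                chain.append(cur)
                kids = sorted(children[cur])
                if len(kids) == 1:
                    cur = kids[0]
                else:
                    break
            pts = np.array([nodes[n][0] for n in chain])
            if pts.shape[0] >= 2:
                paths.append(
                    AxonPath(points=_subdivide_segments(pts),
                             trace_id=f"{stem}#{len(paths)}")
                )
            if children[cur]:
                stack.append((cur, [cur]))
    if not paths:
        raise FormatError("SWC file contains no segment with >= 2 nodes")
    return paths


def write_swc(path_obj: AxonPath, out_path, radius: float = 0.25) -> None:
    """Write an unbranched :class:`AxonPath` as a standard 7-column SWC file."""
    pts = path_obj.points
    with open(out_path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i, (x, y, z) in enumerate(pts, start=1):
            parent = -1 if i == 1 else i - 1
            fh.write(f"{i} 2 {x:.6f} {y:.6f} {z:.6f} {radius:.3f} {parent}\n")


# ---------------------------------------------------------------------------
# resampling and profile extraction
# ---------------------------------------------------------------------------

def resample_path(path: AxonPath, step: float = DEFAULT_STEP_UM) -> ResampledPath:
    """Resample a polyline at uniform arc-length spacing, endpoints preserved.

    The realized step is adjusted to the nearest value that divides the
    total length exactly, so both endpoints are sample points. If ``step``
    exceeds the total length, the result degenerates to the two endpoints
    and is flagged.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    L = path.total_length
    degenerate = step > L
    n = max(1, int(round(L / step)))
    s_new = np.linspace(0.0, L, n + 1)
    arc = path.arc_length
    samples = np.stack(
        [np.interp(s_new, arc, path.points[:, k]) for k in range(3)], axis=1
    )
    return ResampledPath(
        samples=samples, step=L / n, source_trace_id=path.trace_id,
        degenerate=degenerate,
    )


def _disc_offsets(radius: float, n_radii: int, n_angles: int) -> np.ndarray:
    """Unit-disc sample offsets as (m, 2) coefficients for the two normals."""
    offs = [(0.0, 0.0)]
    if radius > 0:
        for k in range(1, n_radii + 1):
            r = radius * k / n_radii
            for a in range(n_angles):
                th = 2 * np.pi * a / n_angles
                offs.append((r * np.cos(th), r * np.sin(th)))
    return np.array(offs)


def extract_profile(
    stack: SessionStack,
    rpath: ResampledPath,
    radius: float = DEFAULT_EXTRACTION_RADIUS,
    n_radii: int = 3,
    n_angles: int = 8,
) -> IntensityProfile:
    """Extract the intensity profile I(s) along a resampled axon path.

    At each sample the intensity is the maximum trilinearly interpolated
    voxel value over a disc of the given radius oriented normal to the
    local path tangent (``radius=0`` reduces to centreline interpolation).
    The max statistic is robust to sub-voxel tracing error; interpolation
    is performed in anisotropic world coordinates. Samples whose centre
    falls outside the stack are masked (NaN).
    """
    pts = rpath.samples
    m = pts.shape[0]

    # central-difference tangents
    tang = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    zero = norms[:, 0] < 1e-12
    norms[zero] = 1.0
    tang = tang / norms
    tang[zero] = np.array([0.0, 0.0, 1.0])  # degenerate: arbitrary frame

    # orthonormal frame per sample: n1 in-plane-ish, n2 completes the triad
    ez = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(tang, ez)
    bad = np.linalg.norm(n1, axis=1) < 1e-6
    if np.any(bad):
        n1[bad] = np.cross(tang[bad], np.array([1.0, 0.0, 0.0]))
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)

    offs = _disc_offsets(radius, n_radii, n_angles)  # (k, 2)
    k = offs.shape[0]
    # world positions of all disc samples: (m, k, 3)
    world = (
        pts[:, None, :]
        + offs[None, :, 0, None] * n1[:, None, :]
        + offs[None, :, 1, None] * n2[:, None, :]
    )

    vox = np.array([stack.voxel_xy, stack.voxel_xy, stack.voxel_z])
    idx = world / vox - 0.5  # fractional voxel indices (x, y, z)
    nz, ny, nx = stack.voxels.shape
    hi = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    inside = np.all((idx >= 0) & (idx <= hi), axis=-1)  # (m, k)
    if not np.any(inside[:, 0]):
        raise EmptyProfileError("trace lies entirely outside the stack")

    coords = np.stack(
        [idx[..., 2].ravel(), idx[..., 1].ravel(), idx[..., 0].ravel()]
    )
    vals = map_coordinates(
        stack.voxels.astype(np.float32), coords, order=1, mode="nearest"
    ).reshape(m, k)
    vals = np.where(inside, vals, -np.inf)
    intensity = np.max(vals, axis=1)
    intensity[~inside[:, 0]] = np.nan
    intensity = np.where(np.isneginf(intensity), np.nan, intensity)
    return IntensityProfile(
        s=rpath.s, intensity=intensity,
        session_day=stack.session_day, extraction_radius=radius,
    )
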