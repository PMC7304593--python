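"""Ground-truth longitudinal axon scenes and their rendering into 3D stacks.

The generator builds a known answer for every downstream stage: an axon
centerline confined to the imaging field, an en-passant bouton population
placed along it, per-session bouton fates (persistence, elimination,
formation, optional reappearance) and sizes, and a noisy (or noise-free)
fluorescence stack per imaging session plus the SWC trace.

The forward model: the axon shaft is a Gaussian tube of peak amplitude
``shaft_amplitude``; each bouton present in a session adds a 3D Gaussian
blob centred on the axon whose peak raises the local intensity to
``shaft_amplitude * w`` for true bouton weight ``w``. A noise-free render
followed by profile extraction and weight computation therefore returns
the true weight (the calibration contract the detection tests rely on).

Default study conditions emulate chronic two-photon imaging of long-range
axons in cortical layer 1: ~200 um of traced axon per field, bouton
linear density 0.12 um^-1, lognormal bouton weights (median ~4 for
thalamocortical-like axons, ~3 for corticocortical-like axons), and
imaging sessions on days 0, 2, 4 and 7.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .profiles import (
    AxonPath,
    SessionStack,
    DEFAULT_VOXEL_XY,
    DEFAULT_VOXEL_Z,
)

FATES = (
    "preexisting_persistent",
    "preexisting_eliminated",
    "formed",
    "transient",
    "reappearing",
)


class SceneConsistencyError(ValueError):
    """Raised when scene pieces disagree (e.g. a bouton off its path)."""


# ---------------------------------------------------------------------------
# parameters and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class DynamicsParams:
    """Ground-truth bouton population dynamics.

    density
        Boutons per um of axon (0.12 matches thalamocortical axons in
        cortical layer 1).
    size_log_mean, size_log_sd
        Parameters of the lognormal day-0 bouton-weight distribution
        (dimensionless weight units). ``log(4)`` gives median weight 4,
        comfortably above the putative-bouton threshold of 2.
    size_min
        Lower truncation of the weight distribution (2.0): a bouton is by
        definition a swelling of weight > 2, and reported densities count
        such structures, so ground-truth boutons are drawn above it.
    formation_prob_per_interval
        Expected newly formed boutons per interval, as a fraction of the
        bouton count in the previous session.
    elimination_prob_per_interval
        Per-interval probability that a present bouton is eliminated. The
        default solves (1 - e)^3 = 0.85, i.e. ~85% of pre-existing boutons
        survive a three-interval / 7-day experiment.
    size_drift_sd
        SD of the per-interval multiplicative lognormal size drift of
        surviving boutons (free parameter; chronic imaging shows bouton
        sizes fluctuate modestly between sessions).
    reappear_prob
        Per-interval probability that an eliminated bouton reappears at
        its previous position (identity-preserving reappearance).
    min_spacing_um
        Minimum inter-bouton spacing enforced at placement, so detection
        separability does not confound rate recovery (the cross-session
        identity tolerance is 0.7 um; 2 um keeps boutons unambiguous).
    end_margin_um
        Boutons are kept this far from the trace endpoints.
    """

    density: float = 0.12
    size_log_mean: float = float(np.log(4.0))
    size_log_sd: float = 0.35
    formation_prob_per_interval: float = 0.08
    elimination_prob_per_interval: float = 1.0 - 0.85 ** (1.0 / 3.0)
    size_drift_sd: float = 0.05
    reappear_prob: float = 0.0
    size_min: float = 2.0
    session_days: tuple[int, ...] = (0, 2, 4, 7)
    min_spacing_um: float = 2.0
    end_margin_um: float = 1.0

    def __post_init__(self):
        for name in ("formation_prob_per_interval",
                     "elimination_prob_per_interval", "reappear_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.density < 0:
            raise ValueError("density must be nonnegative")
        days = tuple(int(d) for d in self.session_days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session_days must be strictly increasing from 0")
        self.session_days = days


@dataclass
class ImagingParams:
    """Acquisition geometry and noise for the rendered stacks.

    Defaults follow high-resolution two-photon imaging of layer-1 axons
    (1024 x 1024 pixels at 0.11 um/pixel, 0.7 um z-step, ~30 planes);
    ``desk()`` returns a smaller field sized to hold a folded ~200 um
    axon for simulation studies.
    """

    voxel_xy: float = DEFAULT_VOXEL_XY
    voxel_z: float = DEFAULT_VOXEL_Z
    field_pixels: tuple[int, int] = (1024, 1024)  # (nx, ny)
    n_planes: int = 30
    psf_sigma_xy: float = 0.4   # um; PSF-convolved bouton blob sigma
    psf_sigma_z: float = 1.0    # um
    shaft_sigma: float = 0.25   # um; intrinsic shaft tube radius sigma
    shaft_amplitude: float = 100.0  # photon-count scale
    noise_model: str = "poisson"    # poisson | gaussian | none
    gaussian_noise_sd: float = 5.0  # counts, for noise_model="gaussian"

    def __post_init__(self):
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @classmethod
    def desk(cls, noise_model: str = "none", field_pixels=(360, 360),
             n_planes: int = 10, **kw) -> "ImagingParams":
        """A reduced field for simulation studies (~40 x 40 x 7 um)."""
        return cls(field_pixels=field_pixels, n_planes=n_planes,
                   noise_model=noise_model, **kw)

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_pixels[0] * self.voxel_xy,
                self.field_pixels[1] * self.voxel_xy)

    @property
    def depth_um(self) -> float:
        return self.n_planes * self.voxel_z

    # effective tube cross-section after PSF convolution
    @property
    def tube_sigma_xy(self) -> float:
        return float(np.hypot(self.shaft_sigma, self.psf_sigma_xy))

    @property
    def tube_sigma_z(self) -> float:
        return float(np.hypot(self.shaft_sigma, self.psf_sigma_z))


@dataclass
class GroundTruthBouton:
    """One physical bouton with its per-session true weights and fate."""

    bouton_id: int
    position_s: float  # arc-length coordinate on the parent path (um)
    amplitude_by_session: dict[int, float] = field(default_factory=dict)
    fate: str = "preexisting_persistent"

    def __post_init__(self):
        if any(a < 0 for a in self.amplitude_by_session.values()):
            raise ValueError("amplitudes must be nonnegative")
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")

    def present(self, day: int) -> bool:
        return self.amplitude_by_session.get(day, 0.0) > 0.0


@dataclass
class AxonScene:
    """A ground-truth longitudinal scene: one axon, its boutons, parameters."""

    path: AxonPath
    boutons: list[GroundTruthBouton]
    dynamics: DynamicsParams
    imaging: ImagingParams
    seed: int = 0
    scene_id: str = "scene0"
    #: per-session rigid arc-length offset (um) applied to bouton positions
    #: at render time; emulates session-to-session registration error
    arc_offset_by_session: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# axon path generation
# ---------------------------------------------------------------------------

def _open_walk(rng, length_um, step_um, turn_sd):
    """Unconfined planar random walk with the given heading-turn SD."""
    n_steps = max(2, int(round(length_um / step_um)))
    pos = np.zeros(2)
    theta = 0.0
    pts = [pos.copy()]
    for _ in range(n_steps):
        theta += rng.normal(0.0, turn_sd)
        pos = pos + step_um * np.array([np.cos(theta), np.sin(theta)])
        pts.append(pos.copy())
    return np.array(pts)


def _serpentine(rng, length_um, step_um, lo, hi, spacing, wiggle_amp,
                wiggle_corr_um=5.0):
    """Folded course through the box [lo, hi] with guaranteed clearance.

    Straight passes parallel to the box's long side, separated by
    ``spacing`` and joined by half-circle turns of radius spacing / 2,
    with smooth random lateral wiggle of amplitude ``wiggle_amp`` on the
    straights (tapered out at the turns). Randomized by orientation
    (axis swap / mirrors) and the transverse starting position. The
    remaining self-clearance is spacing - 2 * wiggle_amp.
    """
    r = spacing / 2.0
    x0, x1 = lo[0] + r, hi[0] - r
    if x1 - x0 < step_um:
        raise ValueError("field too small for a serpentine pass")
    pass_len = x1 - x0
    per_pass = pass_len + np.pi * r
    n_pass = int(np.ceil((length_um + pass_len) / per_pass)) + 1
    span = (n_pass - 1) * spacing
    y_lo = lo[1] + wiggle_amp
    y_hi = hi[1] - wiggle_amp - span
    if y_hi < y_lo:
        raise ValueError(
            f"axon of {length_um} um does not fit the field at "
            f"{spacing} um pass spacing"
        )
    y0 = rng.uniform(y_lo, y_hi)

    pts = []
    mode = []  # 1 on straights, 0 on turns
    for k in range(n_pass):
        y = y0 + k * spacing
        xs = np.arange(x0, x1 + step_um / 2, step_um)
        if k % 2 == 1:
            xs = xs[::-1]
        for x in xs:
            pts.append((x, y))
            mode.append(1)
        if k < n_pass - 1:
            cx = x1 if k % 2 == 0 else x0
            cy = y + r
            dphi = step_um / r
            sign = 1.0 if k % 2 == 0 else -1.0
            for phi in np.arange(dphi, np.pi, dphi):
                pts.append((cx + sign * r * np.sin(phi), cy - r * np.cos(phi)))
                mode.append(0)
    pts = np.array(pts)
    mode = np.array(mode, dtype=float)

    if wiggle_amp > 0:
        from scipy.ndimage import gaussian_filter1d
        sigma = max(1.0, wiggle_corr_um / step_um)
        noise = gaussian_filter1d(rng.normal(size=len(pts)), sigma,
                                  mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = np.clip(noise / (3.0 * sd), -1.0, 1.0) * wiggle_amp
        taper = gaussian_filter1d(mode, max(1.0, 1.5 / step_um))
        pts[:, 1] += noise * taper * mode

    # random orientation: mirrors and axis swap
    for axis in (0, 1):
        if rng.random() < 0.5:
            pts[:, axis] = lo[axis] + hi[axis] - pts[:, axis]
    if rng.random() < 0.5 and (hi[0] - lo[0]) == (hi[1] - lo[1]):
        pts = pts[:, ::-1].copy()

    # truncate at the requested arc length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    stop = int(np.searchsorted(arc, length_um))
    return pts[: max(stop + 1, 2)]


def generate_axon_path(
    length_um: float,
    tortuosity: float = 0.3,
    step_um: float = 0.5,
    seed=None,
    field_um: tuple[float, float] | None = None,
    z_um: float | None = None,
    margin_um: float = 2.0,
    self_avoid_um: float = 2.0,
    trace_id: str = "axon",
) -> AxonPath:
    """Generate a random planar axon centerline of the requested arc length.

    Without a field the heading performs a Gaussian random walk whose
    per-step turn SD is ``tortuosity * sqrt(step_um)`` radians
    (``tortuosity=0`` gives a straight path). With ``field_um`` the axon
    folds through the field on a randomly oriented serpentine course that
    stays ``margin_um`` inside the bounds and keeps at least
    ``self_avoid_um`` lateral clearance from its own earlier course, with
    tortuosity expressed as smooth lateral wiggle; this guarantees that
    distinct stretches of axon never blur together in the rendered
    stacks. The path lies at constant depth ``z_um`` (0 by default).
    """
    if length_um <= 0 or step_um <= 0:
        raise ValueError("length_um and step_um must be positive")
    if not 0.0 <= tortuosity < 1.0:
        raise ValueError("tortuosity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    z0 = 0.0 if z_um is None else float(z_um)

    if field_um is None:
        turn_sd = tortuosity * np.sqrt(step_um)
        pts = _open_walk(rng, length_um, step_um, turn_sd)
    else:
        fx, fy = field_um
        if fx <= 2 * margin_um or fy <= 2 * margin_um:
            raise ValueError("field too small for the requested margin")
        lo = np.array([margin_um, margin_um])
        hi = np.array([fx - margin_um, fy - margin_um])
        wiggle_amp = tortuosity * 1.5
        spacing = self_avoid_um + 2 * wiggle_amp + 0.6
        pts = _serpentine(rng, length_um, step_um, lo, hi, spacing,
                          wiggle_amp)

    xyz = np.column_stack([pts, np.full(len(pts), z0)])
    return AxonPath(points=xyz, trace_id=trace_id)


# ---------------------------------------------------------------------------
# bouton placement and longitudinal evolution
# ---------------------------------------------------------------------------

def _draw_weight(rng, params, max_tries=1000):
    """Lognormal bouton weight, truncated below at params.size_min."""
    for _ in range(max_tries):
        w = float(rng.lognormal(params.size_log_mean, params.size_log_sd))
        if w > params.size_min:
            return w
    return params.size_min + 1e-6


def _draw_spaced_positions(rng, n, lo, hi, existing, min_spacing, max_tries=200):
    """Sequentially draw up to n uniform positions in [lo, hi] respecting spacing."""
    placed = list(existing)
    out = []
    for _ in range(n):
        for _try in range(max_tries):
            s = rng.uniform(lo, hi)
            if not placed or min(abs(s - p) for p in placed) >= min_spacing:
                placed.append(s)
                out.append(s)
                break
    return out


def place_boutons(path: AxonPath, params: DynamicsParams, seed=None
                  ) -> list[GroundTruthBouton]:
    """Place day-0 boutons along the path.

    Positions follow a homogeneous Poisson process of rate ``density``
    along arc length (count ~ Poisson(density * L)), realized by
    sequential rejection so the minimum inter-bouton spacing holds while
    the expected count stays ``density * L``. Day-0 weights are drawn
    lognormal(size_log_mean, size_log_sd).
    """
    rng = np.random.default_rng(seed)
    L = path.total_length
    n = rng.poisson(params.density * L)
    lo = min(params.end_margin_um, L / 2)
    hi = max(L - params.end_margin_um, L / 2)
    positions = _draw_spaced_positions(
        rng, n, lo, hi, [], params.min_spacing_um
    )
    day0 = params.session_days[0]
    boutons = []
    for i, s in enumerate(sorted(positions)):
        amp = _draw_weight(rng, params)
        boutons.append(GroundTruthBouton(
            bouton_id=i, position_s=float(s),
            amplitude_by_session={day0: amp},
        ))
    return boutons


def _classify_fate(amps: list[float]) -> str:
    present = [a > 0 for a in amps]
    ever_elim = any((not p) and any(present[:i]) for i, p in enumerate(present))
    reappeared = any(
        p and (not present[i - 1]) and any(present[:i - 1])
        for i, p in enumerate(present) if i >= 1
    )
    if reappeared:
        return "reappearing"
    if present[0]:
        return "preexisting_eliminated" if ever_elim else "preexisting_persistent"
    return "transient" if ever_elim else "formed"


def evolve_sessions(
    boutons: list[GroundTruthBouton],
    params: DynamicsParams,
    length_um: float,
    seed=None,
) -> list[GroundTruthBouton]:
    """Evolve a day-0 bouton population over the session schedule.

    Per interval each present bouton is eliminated with
    ``elimination_prob_per_interval`` (weight 0 thereafter unless it
    reappears with ``reappear_prob``); survivors drift multiplicatively by
    ``exp(N(0, size_drift_sd))``; new boutons appear as
    Binomial(n_previous, formation_prob_per_interval) at positions
    respecting the minimum spacing against all boutons ever placed. Fates
    are labelled from the realized amplitude sequences. Returns the same
    list, mutated and possibly extended.
    """
    rng = np.random.default_rng(seed)
    days = params.session_days
    positions_all = [b.position_s for b in boutons]
    next_id = max((b.bouton_id for b in boutons), default=-1) + 1
    lo = min(params.end_margin_um, length_um / 2)
    hi = max(length_um - params.end_margin_um, length_um / 2)

    for d_prev, d in zip(days, days[1:]):
        n_prev = 0
        for b in boutons:
            a_prev = b.amplitude_by_session.get(d_prev, 0.0)
            if a_prev > 0:
                n_prev += 1
                if rng.random() < params.elimination_prob_per_interval:
                    b.amplitude_by_session[d] = 0.0
                else:
                    drift = np.exp(rng.normal(0.0, params.size_drift_sd)) \
                        if params.size_drift_sd > 0 else 1.0
                    b.amplitude_by_session[d] = a_prev * drift
            else:
                was_present = any(
                    b.amplitude_by_session.get(dd, 0.0) > 0
                    for dd in days if dd < d_prev or dd == d_prev
                )
                if was_present and rng.random() < params.reappear_prob:
                    last = max(
                        (b.amplitude_by_session[dd] for dd in days
                         if dd < d and b.amplitude_by_session.get(dd, 0) > 0),
                    )
                    b.amplitude_by_session[d] = last
                else:
                    b.amplitude_by_session[d] = 0.0
        n_new = rng.binomial(n_prev, params.formation_prob_per_interval) \
            if n_prev > 0 else 0
        for s in _draw_spaced_positions(rng, n_new, lo, hi, positions_all,
                                        params.min_spacing_um):
            positions_all.append(s)
            amp = _draw_weight(rng, params)
            b = GroundTruthBouton(
                bouton_id=next_id, position_s=float(s),
                amplitude_by_session={dd: 0.0 for dd in days if dd < d},
            )
            b.amplitude_by_session[d] = amp
            boutons.append(b)
            next_id += 1

    for b in boutons:
        amps = [b.amplitude_by_session.get(d, 0.0) for d in days]
        b.fate = _classify_fate(amps)
    return boutons


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _voxel_centers(imaging: ImagingParams):
    nx, ny = imaging.field_pixels
    xs = (np.arange(nx) + 0.5) * imaging.voxel_xy
    ys = (np.arange(ny) + 0.5) * imaging.voxel_xy
    zs = (np.arange(imaging.n_planes) + 0.5) * imaging.voxel_z
    return xs, ys, zs


def render_tube(path: AxonPath, imaging: ImagingParams) -> np.ndarray:
    """Render the axon shaft as a Gaussian tube (peak 1.0 on the centreline).

    The tube value at a voxel is ``exp(-d^2 / (2 sigma_xy^2))`` where d is
    the distance to the centerline measured in coordinates with z scaled
    by ``sigma_xy / sigma_z`` (anisotropic cross-section). Planar paths
    (constant z) use an exact separable 2D distance field; general paths
    fall back to a 3D nearest-sample query.
    """
    s_xy = imaging.tube_sigma_xy
    s_z = imaging.tube_sigma_z
    # dense samples so nearest-sample distance ~ distance to the curve
    arc = path.arc_length
    n_dense = max(2, int(np.ceil(arc[-1] / 0.05)) + 1)
    s_dense = np.linspace(0.0, arc[-1], n_dense)
    dense = path.point_at(s_dense)

    xs, ys, zs = _voxel_centers(imaging)
    nx, ny, nz = xs.size, ys.size, zs.size

    z_span = dense[:, 2].max() - dense[:, 2].min()
    if z_span < 1e-9:
        z0 = dense[0, 2]
        tree = cKDTree(dense[:, :2])
        gx, gy = np.meshgrid(xs, ys, indexing="xy")  # (ny, nx)
        d2d, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]),
                            workers=-1)
        lateral = np.exp(-(d2d ** 2) / (2 * s_xy ** 2)).reshape(ny, nx)
        axial = np.exp(-((zs - z0) ** 2) / (2 * s_z ** 2))
        vol = axial[:, None, None] * lateral[None, :, :]
        return vol.astype(np.float32)

    scale = s_xy / s_z
    scaled = dense.copy()
    scaled[:, 2] *= scale
    tree = cKDTree(scaled)
    gz, gy, gx = np.meshgrid(zs * scale, ys, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = tree.query(pts, workers=-1,
                      distance_upper_bound=6 * s_xy)
    d = np.where(np.isfinite(d), d, np.inf)
    vol = np.exp(-(d ** 2) / (2 * s_xy ** 2)).reshape(nz, ny, nx)
    return vol.astype(np.float32)


def _stamp_blob(vol, centre, amplitude, imaging: ImagingParams, cutoff=4.0):
    """Add a 3D Gaussian blob (separable, anisotropic) in a local window."""
    sx = imaging.psf_sigma_xy
    sz = imaging.psf_sigma_z
    xs, ys, zs = _voxel_centers(imaging)
    wx = cutoff * sx
    wz = cutoff * sz
    ix = np.searchsorted(xs, [centre[0] - wx, centre[0] + wx])
    iy = np.searchsorted(ys, [centre[1] - wx, centre[1] + wx])
    iz = np.searchsorted(zs, [centre[2] - wz, centre[2] + wz])
    if ix[0] >= ix[1] or iy[0] >= iy[1] or iz[0] >= iz[1]:
        return
    gx = np.exp(-((xs[ix[0]:ix[1]] - centre[0]) ** 2) / (2 * sx ** 2))
    gy = np.exp(-((ys[iy[0]:iy[1]] - centre[1]) ** 2) / (2 * sx ** 2))
    gz = np.exp(-((zs[iz[0]:iz[1]] - centre[2]) ** 2) / (2 * sz ** 2))
    vol[iz[0]:iz[1], iy[0]:iy[1], ix[0]:ix[1]] += (
        amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    ).astype(vol.dtype)


def render_stack(
    path: AxonPath,
    boutons: list[GroundTruthBouton],
    session_day: int,
    imaging: ImagingParams,
    arc_offset: float = 0.0,
    tube: np.ndarray | None = None,
    seed=None,
) -> SessionStack:
    """Render one session's stack: shaft tube + bouton blobs + noise.

    A bouton of true weight w adds a blob of peak ``(w - 1) *
    shaft_amplitude`` at its (arc-offset-shifted) position, so the
    peak-to-local-shaft intensity ratio equals w. ``tube`` may carry a
    precomputed :func:`render_tube` result for the same path/imaging to
    amortize the shaft render across sessions.
    """
    L = path.total_length
    for b in boutons:
        if not (0.0 <= b.position_s <= L + 1e-9):
            raise SceneConsistencyError(
                f"bouton {b.bouton_id} at s={b.position_s} is off the path"
            )
    if tube is None:
        tube = render_tube(path, imaging)
    vol = (imaging.shaft_amplitude * tube).astype(np.float32)

    for b in boutons:
        w = b.amplitude_by_session.get(session_day, 0.0)
        if w <= 0.0:
            continue
        s = float(np.clip(b.position_s + arc_offset, 0.0, L))
        centre = path.point_at(s)
        _stamp_blob(vol, centre, (w - 1.0) * imaging.shaft_amplitude, imaging)

    vol = np.clip(vol, 0.0, None)
    if imaging.noise_model == "poisson":
        rng = np.random.default_rng(seed)
        vol = rng.poisson(vol).astype(np.float32)
    elif imaging.noise_model == "gaussian":
        rng = np.random.default_rng(seed)
        vol = np.clip(
            vol + rng.normal(0.0, imaging.gaussian_noise_sd, vol.shape),
            0.0, None,
        ).astype(np.float32)
    return SessionStack(
        voxels=vol, voxel_xy=imaging.voxel_xy, voxel_z=imaging.voxel_z,
        session_day=session_day,
    )


# ---------------------------------------------------------------------------
# scene assembly and serialization
# ---------------------------------------------------------------------------

def generate_scene(
    seed: int,
    dynamics: DynamicsParams | None = None,
    imaging: ImagingParams | None = None,
    length_um: float = 200.0,
    tortuosity: float = 0.3,
    scene_id: str | None = None,
    arc_offset_by_session: dict[int, float] | None = None,
) -> AxonScene:
    """Build a complete ground-truth scene from a single seed.

    Child seeds for the path, placement and evolution stages are derived
    from the master seed with a spawning seed sequence, so identical seeds
    give bit-identical scenes.
    """
    dynamics = dynamics or DynamicsParams()
    imaging = imaging or ImagingParams.desk()
    ss = np.random.SeedSequence(seed)
    s_path, s_place, s_evolve = ss.spawn(3)
    path = generate_axon_path(
        length_um, tortuosity=tortuosity, seed=s_path,
        field_um=imaging.field_um, z_um=imaging.depth_um / 2.0,
        trace_id=scene_id or f"scene{seed}",
    )
    boutons = place_boutons(path, dynamics, seed=s_place)
    evolve_sessions(boutons, dynamics, path.total_length, seed=s_evolve)
    return AxonScene(
        path=path, boutons=boutons, dynamics=dynamics, imaging=imaging,
        seed=seed, scene_id=scene_id or f"scene{seed}",
        arc_offset_by_session=dict(arc_offset_by_session or {}),
    )


def render_scene(scene: AxonScene, noise_seed=None
                 ) -> dict[int, SessionStack]:
    """Render every session of a scene, reusing the shaft tube."""
    tube = render_tube(scene.path, scene.imaging)
    out = {}
    entropy = np.random.SeedSequence(
        [scene.seed if noise_seed is None else noise_seed]
    ).spawn(len(scene.dynamics.session_days))
    for child, day in zip(entropy, scene.dynamics.session_days):
        out[day] = render_stack(
            scene.path, scene.boutons, day, scene.imaging,
            arc_offset=scene.arc_offset_by_session.get(day, 0.0),
            tube=tube, seed=child,
        )
    return out


def ground_truth_frame(scene: AxonScene) -> pd.DataFrame:
    """Ground truth as a tidy table: one row per bouton per session."""
    rows = []
    for b in scene.boutons:
        for day in scene.dynamics.session_days:
            rows.append({
                "bouton_id": b.bouton_id,
                "session_day": day,
                "position_s": b.position_s,
                "true_weight": b.amplitude_by_session.get(day, 0.0),
                "fate": b.fate,
            })
    cols = ["bouton_id", "session_day", "position_s", "true_weight", "fate"]
    return pd.DataFrame(rows, columns=cols)


def write_scene(scene: AxonScene, out_dir) -> dict:
    """Write per-session TIFFs (+ YAML sidecars), the SWC trace, the
    ground-truth CSV and a scene parameter file; returns the rendered
    stacks and written file paths."""
    import tifffile

    from .profiles import write_swc

    os.makedirs(out_dir, exist_ok=True)
    stacks = render_scene(scene)
    files = {"stacks": {}, "stack_meta": {}}
    for day, stack in stacks.items():
        tif = os.path.join(out_dir, f"session_day{day:03d}.tif")
        tifffile.imwrite(tif, stack.voxels)
        sidecar = os.path.splitext(tif)[0] + ".yaml"
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {"voxel_xy": stack.voxel_xy, "voxel_z": stack.voxel_z,
                 "session_day": int(day)}, fh)
        files["stacks"][day] = tif
        files["stack_meta"][day] = sidecar

    swc = os.path.join(out_dir, "trace.swc")
    write_swc(scene.path, swc)
    files["trace"] = swc

    csv = os.path.join(out_dir, "ground_truth.csv")
    ground_truth_frame(scene).to_csv(csv, index=False)
    files["ground_truth"] = csv

    meta = os.path.join(out_dir, "scene.yaml")
    with open(meta, "w") as fh:
        yaml.safe_dump({
            "scene_id": scene.scene_id,
            "seed": int(scene.seed),
            "dynamics": asdict(scene.dynamics) | {
                "session_days": list(scene.dynamics.session_days)},
            "imaging": asdict(scene.imaging) | {
                "field_pixels": list(scene.imaging.field_pixels)},
            "arc_offset_by_session": {
                int(k): float(v)
                for k, v in scene.arc_offset_by_session.items()},
        }, fh)
    files["meta"] = meta
    files["rendered"] = stacks
    return files
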