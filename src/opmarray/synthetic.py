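"""Synthetic heads, scanner-cast-like OPM arrays and simulated recordings.

Everything the scoring and search pipeline needs can be generated here
without external data.  The default protocol is a 13-channel OPM patch over
sensorimotor cortex recording a single 10 Hz sinusoidal dipolar source of
10 nAm for 1 s, with additive Gaussian white sensor noise of 100 fT RMS.

Real anatomy is replaced by parametric surfaces: the inner skull is a
sphere (or mild ellipsoid) and the source surface lies 10 mm interior to
it.  The ``two_surface`` head adds a smooth band-limited radial corrugation
to the source surface so that dipole orientations (surface normals) are not
purely radial -- the feature of a folded cortex that makes sources visible
to a spherical conductor.  Sensors sit 6.5 mm above a scalp surface offset
10 mm from the inner skull, oriented along the local surface normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .forward import HeadModel, LeadField, SourceSpace, compute_leadfield, \
    fit_sphere
from .geometry import Sensor, SensorArray
from .inversion import DataMatrix, SourceEstimate

__all__ = [
    "SimulationSpec",
    "make_head",
    "make_array",
    "simulate_recording",
    "standard_setup",
]

SCALP_OFFSET_M = 0.010      # inner skull -> scalp
SOURCE_DEPTH_M = 0.010      # inner skull -> source surface
MNI_HEAD_RADIUS_M = 0.080   # nominal radius the MNI-like target is scaled by


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the simulated recording protocol."""

    n_channels: int = 13
    source_location_mm: tuple = (46.0, -25.0, 60.0)  # MNI-like, scaled to head
    source_freq_hz: float = 10.0
    dipole_moment_am: float = 10e-9
    noise_rms_t: float = 100e-15
    duration_s: float = 1.0
    sample_rate_hz: float = 1000.0
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("source_freq_hz", "dipole_moment_am", "noise_rms_t",
                     "duration_s", "sample_rate_hz"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_channels < 1 or self.n_trials < 1:
            raise ValueError("n_channels and n_trials must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


def _icosphere_for(n_vertices: int, radius: float) -> trimesh.Trimesh:
    """Smallest icosphere with at least ``n_vertices`` (42, 162, 642, ...)."""
    for sub in range(1, 6):
        if 10 * 4 ** sub + 2 >= n_vertices:
            return trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return trimesh.creation.icosphere(subdivisions=6, radius=radius)


def _corrugation(directions: np.ndarray, rng: np.random.Generator,
                 rms_m: float = 0.003, degree_range=(4, 9)) -> np.ndarray:
    """Smooth band-limited radial displacement field on the unit sphere."""
    from .forward import _real_sh_basis

    lo, hi = degree_range
    basis_full = _real_sh_basis(directions, hi)   # r = 1, so purely angular
    # columns for degrees < lo belong to the leading (lo²-1) entries
    skip = lo * lo - 1
    basis = basis_full[:, skip:]
    coeff = rng.normal(size=basis.shape[1])
    f = basis @ coeff
    f -= f.mean()
    return f * (rms_m / np.sqrt(np.mean(f**2)))


def _sulcal_fold(directions: np.ndarray, target_dir: np.ndarray,
                 radius_m: float, amplitude_m: float = 0.005,
                 wavelength_m: float = 0.016,
                 across_extent_m: float = 0.008,
                 along_extent_m: float = 0.050) -> np.ndarray:
    """Deterministic sulcus-like radial fold through ``target_dir``.

    An extended sinusoidal ridge/valley pair whose zero crossing passes
    through the target, so the surface normal there tilts substantially away
    from radial -- mimicking the tangential orientation of a dipole in a
    sulcal wall (the geometry of the somatosensory N20m generator).  The
    fold runs several centimetres along the ridge direction, like a real
    central sulcus; the across-ridge envelope is tight (a *single* sulcus)
    so the surface has no translational periodicity -- a periodic fold
    would alias: displacing the array by one wavelength would find an
    identical wall, a degeneracy real aperiodic cortex does not have.
    """
    t = target_dir / np.linalg.norm(target_dir)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(t, helper)           # across-ridge direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)               # along-ridge direction
    s = np.arcsin(np.clip(directions @ e1, -1.0, 1.0)) * radius_m
    u = np.arcsin(np.clip(directions @ e2, -1.0, 1.0)) * radius_m
    envelope = np.exp(-0.5 * ((s / across_extent_m) ** 2
                              + (u / along_extent_m) ** 2))
    # suppress the fold on the antipodal hemisphere (arcsin is ambiguous)
    envelope = envelope * (directions @ t > 0)
    return amplitude_m * np.sin(2 * np.pi * s / wavelength_m) * envelope


def make_head(kind: str = "two_surface", radius_m: float = 0.08,
              n_vertices: int = 2562, seed: int = 0,
              fold_target=(46.0, -25.0, 60.0)
              ) -> tuple[trimesh.Trimesh, SourceSpace]:
    """Closed inner-skull surface plus a source space 10 mm interior to it.

    kinds: ``sphere`` (concentric spheres, radial source normals),
    ``ellipsoid`` (axes 0.95/1.0/1.05 of ``radius_m``) and ``two_surface``
    (spherical skull, corrugated cortical-like source surface; the default
    for simulations).  Deterministic per seed.

    The ``two_surface`` source surface carries a seeded random background
    corrugation plus a deterministic sulcus-like fold through the direction
    of ``fold_target`` (the simulated somatosensory site), so the dipole
    there has the tangential orientation of a real sulcal-wall source
    rather than the externally silent radial orientation of a smooth
    sphere.  Pass ``fold_target=None`` to disable the fold.
    """
    if n_vertices < 42:
        raise ValueError("n_vertices must be >= 42")
    rng = np.random.default_rng(seed)
    if kind == "sphere":
        skull = _icosphere_for(n_vertices, radius_m)
        src_mesh = _icosphere_for(n_vertices, radius_m - SOURCE_DEPTH_M)
        normals = src_mesh.vertices / np.linalg.norm(
            src_mesh.vertices, axis=1, keepdims=True)
    elif kind == "ellipsoid":
        skull = _icosphere_for(n_vertices, 1.0)
        axes = radius_m * np.array([0.95, 1.0, 1.05])
        skull = trimesh.Trimesh(skull.vertices * axes, skull.faces,
                                process=False)
        vn = np.asarray(skull.vertex_normals)
        src_mesh = trimesh.Trimesh(skull.vertices - SOURCE_DEPTH_M * vn,
                                   skull.faces, process=False)
        normals = np.asarray(src_mesh.vertex_normals).copy()
    elif kind == "two_surface":
        skull = _icosphere_for(n_vertices, radius_m)
        unit = _icosphere_for(n_vertices, 1.0)
        dirs = np.asarray(unit.vertices)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        r = (radius_m - SOURCE_DEPTH_M) + _corrugation(dirs, rng)
        if fold_target is not None:
            r = r + _sulcal_fold(dirs, np.asarray(fold_target, float),
                                 radius_m - SOURCE_DEPTH_M)
        # keep the cortical surface strictly inside the inner skull
        r = np.clip(r, 0.5 * radius_m, radius_m - 0.002)
        src_mesh = trimesh.Trimesh(dirs * r[:, None], unit.faces,
                                   process=False)
        normals = np.asarray(src_mesh.vertex_normals).copy()
    else:
        raise ValueError(f"unknown head kind {kind!r}")
    # orient normals outward
    flip = np.einsum("ij,ij->i", normals, src_mesh.vertices) < 0
    normals[flip] *= -1
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    sources = SourceSpace(np.asarray(src_mesh.vertices), normals)
    return skull, sources


def make_array(head: trimesh.Trimesh, target, n_sensors: int = 13,
               standoff_m: float = 0.0065, seed: int = 0,
               min_spacing_m: float = 0.025) -> SensorArray:
    """Scanner-cast-like sensor patch over the scalp projection of ``target``.

    Sensors are laid out in concentric rings (1, 6, 12, ...) at arc spacing
    ``min_spacing_m`` on the scalp surface (inner skull + 10 mm), each lifted
    ``standoff_m`` along the local surface normal with its sensitive axis
    along that normal.
    """
    import warnings

    sphere = fit_sphere(head)
    centre = sphere.centre
    r_scalp = sphere.radius + SCALP_OFFSET_M
    target = np.asarray(target, float).reshape(3)
    d0 = target - centre
    d0 = d0 / np.linalg.norm(d0)
    # tangent basis, azimuth seeded
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d0 @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0, 2 * np.pi)

    dirs = [d0]
    ring = 1
    while len(dirs) < n_sensors:
        alpha = ring * min_spacing_m / r_scalp
        if alpha >= np.pi / 2:
            warnings.warn(
                f"scalp patch too small for {n_sensors} sensors at "
                f"{min_spacing_m * 1e3:.0f} mm spacing; placing {len(dirs)}",
                stacklevel=2)
            break
        n_ring = min(6 * ring, n_sensors - len(dirs))
        for j in range(n_ring):
            phi = phi0 + 2 * np.pi * j / max(6 * ring, 1) + ring * 0.2
            t = np.cos(phi) * e1 + np.sin(phi) * e2
            dirs.append(np.cos(alpha) * d0 + np.sin(alpha) * t)
        ring += 1

    sensors = []
    for i, d in enumerate(dirs):
        pos = centre + d * (r_scalp + standoff_m)
        sensors.append(Sensor(pos, d, 1.0, f"opm{i:02d}"))
    return SensorArray(tuple(sensors))


def simulate_recording(spec: SimulationSpec, array: SensorArray,
                       sources: SourceSpace, head: HeadModel,
                       leadfield: LeadField | None = None
                       ) -> tuple[DataMatrix, SourceEstimate]:
    """Simulated sensor data Y = L J_true + noise and the ground truth.

    The dipole is placed at the source vertex nearest the (scaled) target
    location and driven sinusoidally; white Gaussian noise of the specified
    RMS is added per channel and sample, divided by sqrt(n_trials) to model
    trial averaging.
    """
    rng = np.random.default_rng(spec.seed)
    if leadfield is None:
        leadfield = compute_leadfield(array, sources, head)
    target = np.asarray(spec.source_location_mm, float) * 1e-3
    # linear rescale of MNI-like space so the nominal cortical shell
    # (radius ~ MNI head radius) maps onto this head's source surface
    sphere_r = head.radius if head.radius is not None else MNI_HEAD_RADIUS_M
    target = target * ((sphere_r - SOURCE_DEPTH_M) / MNI_HEAD_RADIUS_M)
    dist = np.linalg.norm(sources.positions - target, axis=1)
    vertex = int(np.argmin(dist))
    if dist[vertex] > 0.020:
        raise ValueError(
            f"target lies {dist[vertex] * 1e3:.1f} mm from the nearest "
            "source vertex (limit 20 mm)")
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    s = spec.dipole_moment_am * np.sin(2 * np.pi * spec.source_freq_hz * t)
    Y = np.outer(leadfield.matrix[:, vertex], s)
    sigma = spec.noise_rms_t / np.sqrt(spec.n_trials)
    if sigma > 0:
        Y = Y + sigma * rng.normal(size=Y.shape)
    J = np.zeros((sources.n_sources, spec.n_samples))
    J[vertex] = s
    data = DataMatrix(Y, spec.sample_rate_hz, tuple(array.labels))
    return data, SourceEstimate(J)


def standard_setup(seed: int = 0, spec: SimulationSpec | None = None,
                   head_kind: str = "two_surface", radius_m: float = 0.08,
                   n_vertices: int = 10242, band_hz: tuple = (2.0, 80.0)):
    """Build the full default protocol: head, sources, array, model, data.

    Returns a dict with keys ``skull, sources, array, head, spec, data,
    truth, leadfield``.  The geometry is derived deterministically from
    ``seed``; the noise realisation uses ``spec.seed`` (defaults to a seed
    derived from the same value).  The returned data are band-passed to
    ``band_hz`` (the standard 2-80 Hz inversion band; pass None to skip).
    """
    from .inversion import bandpass

    ss = np.random.SeedSequence(seed)
    geom_seed, noise_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    skull, sources = make_head(head_kind, radius_m, n_vertices, geom_seed)
    head = fit_sphere(skull)
    if spec is None:
        spec = SimulationSpec(seed=noise_seed)
    target = np.asarray(spec.source_location_mm, float)
    target = target / np.linalg.norm(target) * (head.radius - SOURCE_DEPTH_M)
    array = make_array(skull, target, spec.n_channels, seed=geom_seed)
    lf = compute_leadfield(array, sources, head)
    data, truth = simulate_recording(spec, array, sources, head, lf)
    if band_hz is not None:
        data = bandpass(data, *band_hz)
    return dict(skull=skull, sources=sources, array=array, head=head,
                spec=spec, data=data, truth=truth, leadfield=lf)
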