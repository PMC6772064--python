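"""Volume-conductor lead fields for point magnetometers.

Two conductor families are provided:

* homogeneous conducting **sphere** (global or locally fitted), with the
  closed-form Sarvas expression for the external magnetic field of a current
  dipole.  Radially oriented dipoles are externally silent in this model.
* **corrected-sphere single shell**: the sphere field plus a curl-free
  correction expanded in gradients of exterior solid harmonics, whose
  coefficients are fitted so that the normal component of the total field on
  the (realistically shaped) inner-skull surface matches that of the primary
  dipole field in an infinite homogeneous medium.  On the surface of a
  conductor the normal field component is fixed by the primary current alone,
  which is the boundary condition this collocation enforces; for an exactly
  spherical shell the correction vanishes and the model reduces to the
  Sarvas sphere.

All lead fields are in tesla per (ampere metre): entry (c, d) is the signed
field along sensor c's sensitive axis produced by a unit current dipole at
source d along its orientation, scaled by the sensor gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.special import sph_harm_y

from .geometry import SensorArray

__all__ = [
    "SourceSpace",
    "HeadModel",
    "LeadField",
    "fit_sphere",
    "leadfield_sphere",
    "leadfield_single_shell",
    "compute_leadfield",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass(frozen=True)
class SourceSpace:
    """Dipole locations (m) with fixed orientations (cortical normals)."""

    positions: np.ndarray
    orientations: np.ndarray
    areas: np.ndarray | None = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, float))
        ori = np.atleast_2d(np.asarray(self.orientations, float))
        if pos.shape != ori.shape or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions and orientations must both be (Nd, 3)")
        nrm = np.linalg.norm(ori, axis=1)
        if np.any(nrm == 0):
            raise ValueError("source orientations must be non-zero")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori / nrm[:, None])

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class HeadModel:
    """Volume conductor: fitted sphere or corrected-sphere single shell."""

    kind: str  # sphere_global | sphere_local | single_shell
    centre: np.ndarray
    radius: float | None = None
    shell_mesh: trimesh.Trimesh | None = None
    sh_order: int = 8

    def __post_init__(self):
        if self.kind not in ("sphere_global", "sphere_local", "single_shell"):
            raise ValueError(f"unknown head-model kind {self.kind!r}")
        object.__setattr__(self, "centre", np.asarray(self.centre, float).reshape(3))
        if self.kind != "single_shell":
            if self.radius is None or not self.radius > 0:
                raise ValueError("sphere head models need a positive radius")
        else:
            if self.shell_mesh is None:
                raise ValueError("single_shell head model needs a shell mesh")
            if self.sh_order < 1:
                raise ValueError("sh_order must be >= 1")

    @property
    def is_sphere(self) -> bool:
        return self.kind in ("sphere_global", "sphere_local")


@dataclass(frozen=True)
class LeadField:
    """Nc x Nd gain matrix, tesla per unit (1 A·m) dipole."""

    matrix: np.ndarray
    channel_labels: tuple[str, ...] = ()
    head_kind: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if not np.isfinite(m).all():
            raise ValueError("lead field contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# sphere fitting


def fit_sphere(surface, region=None, kind: str = "sphere_global") -> HeadModel:
    """Least-squares sphere fit to a surface, minimising Σ(‖v−c‖−r)².

    Parameters
    ----------
    surface : trimesh.Trimesh or (N, 3) array
        Surface vertices to fit.
    region : array of vertex indices, optional
        Restrict the fit to this subset (local sphere over a patch).
    kind : str
        ``sphere_global`` or ``sphere_local``, recorded on the result.
    """
    if isinstance(surface, trimesh.Trimesh):
        verts = np.asarray(surface.vertices, float)
    else:
        verts = np.atleast_2d(np.asarray(surface, float))
    if region is not None:
        verts = verts[np.asarray(region)]
    if verts.shape[0] < 4:
        raise ValueError("sphere fit needs at least 4 vertices")
    # algebraic (Kasa) initialisation: ‖v‖² = 2 c·v + (r² − ‖c‖²)
    A = np.hstack([2.0 * verts, np.ones((len(verts), 1))])
    b = np.einsum("ij,ij->i", verts, verts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) surface: sphere fit failed")
    c0 = sol[:3]
    r0 = np.sqrt(max(sol[3] + c0 @ c0, 1e-12))

    def resid(p):
        return np.linalg.norm(verts - p[:3], axis=1) - p[3]

    fit = least_squares(resid, np.append(c0, r0), method="lm")
    centre, radius = fit.x[:3], float(fit.x[3])
    if not radius > 0:
        raise ValueError("sphere fit failed: non-positive radius")
    return HeadModel(kind=kind, centre=centre, radius=radius)


# ---------------------------------------------------------------------------
# Sarvas sphere lead field


def _sarvas_field(sensors_rel: np.ndarray, sources_rel: np.ndarray,
                  moments: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of current dipoles in a homogeneous sphere.

    Parameters are positions relative to the sphere centre: ``sensors_rel``
    (Np, 3), ``sources_rel`` (Nd, 3) and dipole ``moments`` (Nd, 3) in A·m.
    Returns (Np, Nd, 3).
    """
    r = sensors_rel[:, None, :]          # (Np,1,3)
    r0 = sources_rel[None, :, :]         # (1,Nd,3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=2)    # (Np,Nd)
    R = np.linalg.norm(sensors_rel, axis=1)[:, None]  # (Np,1)
    adotr = np.einsum("pdk,pk->pd", a_vec, sensors_rel)
    r0dotr = np.einsum("dk,pk->pd", sources_rel, sensors_rel)
    F = a * (R * a + R**2 - r0dotr)
    cF_r = a**2 / R + adotr / a + 2.0 * a + 2.0 * R
    cF_r0 = a + 2.0 * R + adotr / a
    gradF = cF_r[..., None] * r - cF_r0[..., None] * r0
    qxr0 = np.cross(moments, sources_rel)            # (Nd,3)
    # exact silence for radially symmetric configurations: a moment parallel
    # to the source radius, or a source at the centre, produces no external
    # field; zero the cross product so rounding noise cannot leak through
    r0n = np.linalg.norm(sources_rel, axis=1)
    qn = np.linalg.norm(moments, axis=1)
    silent = (r0n < 1e-9) | (
        np.linalg.norm(qxr0, axis=1) < 1e-10 * qn * np.maximum(r0n, 1e-300))
    qxr0 = np.where(silent[:, None], 0.0, qxr0)
    qxr0_dot_r = np.einsum("dk,pk->pd", qxr0, sensors_rel)
    B = (F[..., None] * qxr0[None, :, :] - qxr0_dot_r[..., None] * gradF)
    B *= MU0_OVER_4PI / (F**2)[..., None]
    return B


def _infinite_medium_field(points: np.ndarray, sources: np.ndarray,
                           moments: np.ndarray) -> np.ndarray:
    """Primary field of current dipoles in an infinite homogeneous medium.

    B(x) = mu0/4pi * q × (x − r0) / ‖x − r0‖³; shape (Np, Nd, 3).
    """
    d = points[:, None, :] - sources[None, :, :]
    d3 = np.linalg.norm(d, axis=2) ** 3
    B = np.cross(np.broadcast_to(moments[None, :, :], d.shape), d)
    return MU0_OVER_4PI * B / d3[..., None]


def leadfield_sphere(array: SensorArray, sources: SourceSpace,
                     head: HeadModel) -> LeadField:
    """Sarvas lead field for a homogeneous-sphere conductor."""
    if not head.is_sphere:
        raise ValueError("leadfield_sphere requires a sphere head model")
    src_rel = sources.positions - head.centre
    if head.radius is not None:
        outside = np.linalg.norm(src_rel, axis=1) > head.radius
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} source(s) lie outside the fitted sphere; "
                "the sphere model is invalid there", stacklevel=2)
    B = _sarvas_field(array.positions - head.centre, src_rel,
                      sources.orientations)
    vals = np.einsum("pdk,pk->pd", B, array.orientations)
    vals *= array.gains[:, None]
    return LeadField(vals, tuple(array.labels), head.kind)


# ---------------------------------------------------------------------------
# corrected-sphere single shell


def _real_sh_basis(points_rel: np.ndarray, order: int) -> np.ndarray:
    """Exterior real solid harmonics r^{-(l+1)} S_lm at points, (Np, K).

    K = (order+1)² − 1 basis functions (l = 1..order, m = −l..l); the l = 0
    monopole term is excluded as unphysical for magnetic fields.
    """
    x, y, z = points_rel.T
    r = np.linalg.norm(points_rel, axis=1)
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(1, order + 1):
        rad = r ** (-(l + 1))
        for m in range(-l, l + 1):
            y_c = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                s = y_c.real
            elif m > 0:
                s = np.sqrt(2.0) * (-1.0) ** m * y_c.real
            else:
                s = np.sqrt(2.0) * (-1.0) ** m * y_c.imag
            cols.append(rad * s)
    return np.column_stack(cols)


def _sh_basis_gradients(points_rel: np.ndarray, order: int,
                        step: float = 1e-6) -> np.ndarray:
    """Cartesian gradients of the exterior harmonic basis, (Np, K, 3).

    Central finite differences with a step small relative to head scale;
    the basis is smooth away from the origin so the truncation error is
    ~(step/r)² ≈ 1e-10 relative.
    """
    grads = np.empty((points_rel.shape[0], (order + 1) ** 2 - 1, 3))
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = step
        hi = _real_sh_basis(points_rel + dp, order)
        lo = _real_sh_basis(points_rel - dp, order)
        grads[:, :, k] = (hi - lo) / (2.0 * step)
    return grads


class _ShellCorrector:
    """Precomputed collocation fit for one (head, array) pair.

    Factoring the surface fit out of the per-source loop makes repeated
    lead-field evaluation (perturbation curves, pose search) cheap: only the
    right-hand side depends on the source.
    """

    def __init__(self, head: HeadModel, array: SensorArray):
        mesh = head.shell_mesh
        if not mesh.is_watertight:
            raise ValueError("single-shell model requires a closed shell mesh")
        sphere = fit_sphere(mesh)
        self.centre = sphere.centre
        self.radius = sphere.radius
        self.order = head.sh_order
        pts = np.asarray(mesh.triangles_center, float)
        normals = np.asarray(mesh.face_normals, float)
        # ensure outward orientation
        if np.mean(np.einsum("ij,ij->i", normals, pts - self.centre)) < 0:
            normals = -normals
        self.surf_points = pts
        self.surf_normals = normals
        G = _sh_basis_gradients(pts - self.centre, self.order)
        A = np.einsum("pkj,pj->pk", G, normals)
        # scale columns for conditioning of the collocation solve
        self.col_scale = np.linalg.norm(A, axis=0)
        A = A / self.col_scale
        u, s, vt = np.linalg.svd(A, full_matrices=False)
        cond = s[0] / s[-1]
        if cond > 1e10:
            warnings.warn(
                f"ill-conditioned shell basis (cond={cond:.2e}); "
                "solution regularised by SVD truncation", stacklevel=2)
        keep = s > s[0] * 1e-10
        self.pinv = (vt[keep].T / s[keep]) @ u[:, keep].T   # (K, P)
        Gs = _sh_basis_gradients(array.positions - self.centre, self.order)
        S = np.einsum("ckj,cj->ck", Gs, array.orientations)
        self.sensor_basis = (S / self.col_scale) * array.gains[:, None]

    def correction(self, sources: SourceSpace, block: int = 256) -> np.ndarray:
        """Correction lead field (Nc, Nd) added to the Sarvas term."""
        out = np.empty((self.sensor_basis.shape[0], sources.n_sources))
        for i in range(0, sources.n_sources, block):
            pos = sources.positions[i:i + block] - self.centre
            mom = sources.orientations[i:i + block]
            pts_rel = self.surf_points - self.centre
            b_inf = _infinite_medium_field(pts_rel, pos, mom)
            b_sph = _sarvas_field(pts_rel, pos, mom)
            g = np.einsum("pdk,pk->pd", b_inf - b_sph, self.surf_normals)
            coeff = self.pinv @ g                      # (K, nd)
            out[:, i:i + block] = self.sensor_basis @ coeff
        return out


def leadfield_single_shell(array: SensorArray, sources: SourceSpace,
                           head: HeadModel) -> LeadField:
    """Corrected-sphere (single shell) lead field.

    The Sarvas field of the sphere fitted to the shell mesh, plus a curl-free
    spherical-harmonic correction collocated at the mesh face centres so that
    the normal component of the total field on the shell equals that of the
    primary (infinite-medium) dipole field.
    """
    if head.kind != "single_shell":
        raise ValueError("leadfield_single_shell requires a single_shell model")
    corrector = _ShellCorrector(head, array)
    sphere = HeadModel("sphere_global", corrector.centre, corrector.radius)
    base = leadfield_sphere(array, sources, sphere)
    corr = corrector.correction(sources)
    return LeadField(base.matrix + corr, tuple(array.labels), head.kind)


def compute_leadfield(array: SensorArray, sources: SourceSpace,
                      head: HeadModel) -> LeadField:
    """Dispatch on the head-model kind."""
    if head.is_sphere:
        return leadfield_sphere(array, sources, head)
    return leadfield_single_shell(array, sources, head)
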