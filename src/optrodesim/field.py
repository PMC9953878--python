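"""Bipolar stimulation field, activating function, and volume of tissue activated.

The DBS microelectrode pair is idealized as a current source (+I) and sink
(-I) in an infinite homogeneous isotropic volume conductor of conductivity
K.  Superposing two monopole solutions of Poisson's equation gives the
extracellular potential

    Ve(p) = I / (4 pi K) * (1 / |p - p_src| - 1 / |p - p_sink|)

A finite-difference Poisson solver on the same voxel grid provides an
independent numerical route (7-point stencil, Dirichlet boundary, conjugate
gradients) used to cross-validate the closed form.

Neural activation is predicted by the activating function — the second
spatial difference of Ve along a putative axon axis,

    f(n) = [Ve(n-1) - 2 Ve(n) + Ve(n+1)] / L^2     [V/m^2]

with L the voxel spacing.  The volume of tissue activated (VTA) is the
superlevel set f > threshold.  With threshold exactly 0 the mask is
invariant to the stimulation current (the sign of a field linear in I does
not change with I); a strictly positive threshold yields the
current-dependent VTA volumes of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import InvalidParameterError, VoxelGrid

_AXES = {"x": 0, "y": 1, "z": 2}


class SingularityError(ValueError):
    """A potential was requested at an electrode point."""


class ConvergenceError(RuntimeError):
    """The iterative Poisson solver failed to reach its residual tolerance."""

    def __init__(self, residual: float, tol: float):
        super().__init__(
            f"FD Poisson solver did not converge: residual {residual:.3e} > tol {tol:.3e}"
        )
        self.residual = residual


@dataclass(frozen=True)
class ElectrodePair:
    """Bipolar microelectrode pair: +I at the source, -I at the sink.

    Positions are physical um in the grid frame; the probe's pair spacing
    is 450 um.  ``current_a`` is the pulse amplitude in amperes.
    """

    source_um: tuple[float, float, float]
    sink_um: tuple[float, float, float]
    current_a: float

    def __post_init__(self) -> None:
        if np.allclose(self.source_um, self.sink_um):
            raise InvalidParameterError("source and sink must be distinct points")
        if self.current_a < 0:
            raise InvalidParameterError("current must be non-negative")

    @property
    def separation_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.source_um, self.sink_um)))

    def swapped(self) -> "ElectrodePair":
        return ElectrodePair(self.sink_um, self.source_um, self.current_a)


@dataclass(frozen=True)
class PotentialField:
    """Extracellular potential Ve (volts) sampled at voxel centres."""

    grid: VoxelGrid
    ve: np.ndarray  # (nx, ny, nz), volts
    provenance: str  # "analytic" | "finite-difference"


@dataclass(frozen=True)
class ActivatingFunctionMap:
    """Second difference of Ve along ``axis``, in V/m^2.

    Boundary voxels along the axis carry 0 (no central difference exists).
    """

    grid: VoxelGrid
    f_values: np.ndarray
    axis: str
    spacing_um: float


@dataclass(frozen=True)
class VTAMask:
    """Voxels predicted activated: the superlevel set f > threshold."""

    grid: VoxelGrid
    mask: np.ndarray  # boolean
    threshold_v_per_m2: float

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


def analytic_potential(pair: ElectrodePair, conductivity_s_per_m: float,
                       points_um, r_min_um: float | None = None) -> np.ndarray:
    """Closed-form bipolar potential at arbitrary points.

    Parameters
    ----------
    points_um:
        Array of shape (..., 3) of physical coordinates in um.
    r_min_um:
        If given, distances below this are clamped to it (regularizing the
        1/r singularity at one-voxel scale); otherwise a query at an
        electrode point raises :class:`SingularityError`.

    Returns
    -------
    Potentials in volts, shape ``points_um.shape[:-1]``.
    """
    if conductivity_s_per_m <= 0:
        raise InvalidParameterError("conductivity must be positive")
    pts = np.asarray(points_um, dtype=float)
    r_src = np.linalg.norm(pts - np.asarray(pair.source_um), axis=-1)
    r_snk = np.linalg.norm(pts - np.asarray(pair.sink_um), axis=-1)
    if r_min_um is not None:
        r_src = np.maximum(r_src, r_min_um)
        r_snk = np.maximum(r_snk, r_min_um)
    elif np.any(r_src == 0) or np.any(r_snk == 0):
        raise SingularityError("potential requested at an electrode point")
    scale = pair.current_a / (4.0 * np.pi * conductivity_s_per_m)
    # distances in um -> metres
    return scale * (1.0 / (r_src * 1e-6) - 1.0 / (r_snk * 1e-6))


def potential_on_grid(pair: ElectrodePair, conductivity_s_per_m: float,
                      grid: VoxelGrid, r_min_um: float | None = None) -> PotentialField:
    """Analytic potential evaluated at every voxel centre.

    The singularity clamp defaults to half a voxel edge so that the voxels
    containing the electrodes carry finite values.
    """
    if r_min_um is None:
        r_min_um = grid.voxel_edge_um / 2.0
    cx, cy, cz = grid.centers()
    src = np.asarray(pair.source_um)
    snk = np.asarray(pair.sink_um)
    scale = pair.current_a / (4.0 * np.pi * conductivity_s_per_m)
    ve = np.zeros(grid.shape, dtype=float)
    dx2s = (cx - src[0])[:, None] ** 2
    dy2s = (cy - src[1])[None, :] ** 2
    dx2k = (cx - snk[0])[:, None] ** 2
    dy2k = (cy - snk[1])[None, :] ** 2
    for k, z in enumerate(cz):
        r_s = np.sqrt(dx2s + dy2s + (z - src[2]) ** 2)
        r_k = np.sqrt(dx2k + dy2k + (z - snk[2]) ** 2)
        np.maximum(r_s, r_min_um, out=r_s)
        np.maximum(r_k, r_min_um, out=r_k)
        ve[:, :, k] = scale * (1.0 / (r_s * 1e-6) - 1.0 / (r_k * 1e-6))
    return PotentialField(grid=grid, ve=ve, provenance="analytic")


def _laplacian_dirichlet(shape: tuple[int, int, int], h_m: float) -> sp.csr_matrix:
    """SPD operator A = -Laplacian on the interior of a Dirichlet box."""
    nx, ny, nz = shape
    inv_h2 = 1.0 / h_m**2

    def lap1d(n):
        return sp.diags([np.full(n - 1, -1.0), np.full(n, 2.0), np.full(n - 1, -1.0)],
                        [-1, 0, 1], format="csr")

    ix, iy, iz = sp.identity(nx), sp.identity(ny), sp.identity(nz)
    a = (sp.kron(sp.kron(lap1d(nx), iy), iz)
         + sp.kron(sp.kron(ix, lap1d(ny)), iz)
         + sp.kron(sp.kron(ix, iy), lap1d(nz)))
    return (a * inv_h2).tocsr()


def solve_poisson_fd(grid: VoxelGrid, conductivity_s_per_m: float, pair: ElectrodePair,
                     boundary: str = "analytic-dirichlet", tol: float = 1e-8,
                     max_iter: int = 20000) -> PotentialField:
    """Finite-difference solution of the bipolar Poisson problem.

    Solves ``-lap Ve = (I/K) [delta_src - delta_snk]`` on the voxel lattice
    (7-point stencil, voxel-centred), with the point sources assigned to the
    voxels containing the electrodes.  ``boundary`` selects the Dirichlet
    data on the one-voxel frame: ``"dirichlet-zero"`` (grounded box) or
    ``"analytic-dirichlet"`` (clamped to the closed form, so the interior
    should agree with :func:`analytic_potential` away from the sources).

    Raises
    ------
    ConvergenceError
        If conjugate gradients fails to reach ``tol`` (relative residual).
    """
    if boundary not in ("dirichlet-zero", "analytic-dirichlet"):
        raise InvalidParameterError(f"unknown boundary condition {boundary!r}")
    nx, ny, nz = grid.shape
    if min(nx, ny, nz) < 3:
        raise InvalidParameterError("FD solver needs at least 3 voxels per axis")
    if not (grid.contains(pair.source_um) and grid.contains(pair.sink_um)):
        raise InvalidParameterError("both electrodes must lie inside the grid")

    h_m = grid.voxel_edge_um * 1e-6
    inner_shape = (nx - 2, ny - 2, nz - 2)
    a = _laplacian_dirichlet(inner_shape, h_m)

    b = np.zeros(inner_shape, dtype=float)
    # point sources: delta approximated as 1/h^3 in the containing voxel
    q = pair.current_a / (conductivity_s_per_m * h_m**3)
    for pos, sign in ((pair.source_um, +1.0), (pair.sink_um, -1.0)):
        i, j, k = grid.voxel_of(pos)
        if not (1 <= i <= nx - 2 and 1 <= j <= ny - 2 and 1 <= k <= nz - 2):
            raise InvalidParameterError("electrode voxel lies on the boundary frame")
        b[i - 1, j - 1, k - 1] += sign * q

    ve = np.zeros(grid.shape, dtype=float)
    if boundary == "analytic-dirichlet":
        full = potential_on_grid(pair, conductivity_s_per_m, grid).ve
        ve[0, :, :], ve[-1, :, :] = full[0, :, :], full[-1, :, :]
        ve[:, 0, :], ve[:, -1, :] = full[:, 0, :], full[:, -1, :]
        ve[:, :, 0], ve[:, :, -1] = full[:, :, 0], full[:, :, -1]
        inv_h2 = 1.0 / h_m**2
        b[0, :, :] += ve[0, 1:-1, 1:-1] * inv_h2
        b[-1, :, :] += ve[-1, 1:-1, 1:-1] * inv_h2
        b[:, 0, :] += ve[1:-1, 0, 1:-1] * inv_h2
        b[:, -1, :] += ve[1:-1, -1, 1:-1] * inv_h2
        b[:, :, 0] += ve[1:-1, 1:-1, 0] * inv_h2
        b[:, :, -1] += ve[1:-1, 1:-1, -1] * inv_h2

    b_flat = b.ravel()
    x, info = spla.cg(a, b_flat, rtol=tol, atol=0.0, maxiter=max_iter)
    residual = float(np.linalg.norm(a @ x - b_flat) / max(np.linalg.norm(b_flat), 1e-300))
    if info != 0 or residual > 10 * tol:
        raise ConvergenceError(residual, tol)
    ve[1:-1, 1:-1, 1:-1] = x.reshape(inner_shape)
    return PotentialField(grid=grid, ve=ve, provenance="finite-difference")


def activating_function(field: PotentialField, axis: str = "x") -> ActivatingFunctionMap:
    """Second spatial difference of Ve along an axon axis, in V/m^2.

    The default axis is x; fibers of passage have no preferred stated
    orientation, so the axis is configurable.
    """
    if axis not in _AXES:
        raise InvalidParameterError(f"axis must be one of {sorted(_AXES)}")
    ax = _AXES[axis]
    if field.grid.shape[ax] < 3:
        raise InvalidParameterError("activating function needs >= 3 voxels along axis")
    l_m = field.grid.voxel_edge_um * 1e-6
    ve = field.ve
    f = np.zeros_like(ve)
    lo = [slice(None)] * 3
    mid = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[ax], mid[ax], hi[ax] = slice(0, -2), slice(1, -1), slice(2, None)
    f[tuple(mid)] = (ve[tuple(lo)] - 2.0 * ve[tuple(mid)] + ve[tuple(hi)]) / l_m**2
    return ActivatingFunctionMap(grid=field.grid, f_values=f, axis=axis,
                                 spacing_um=field.grid.voxel_edge_um)


def vta_from_af(af: ActivatingFunctionMap, threshold_v_per_m2: float = 0.0) -> VTAMask:
    """Volume of tissue activated: voxels with f > threshold.

    The literal activation rule is f(n) > 0.  Because f is linear in the
    stimulation current, the zero-threshold mask is identical for every
    positive current; pass a positive threshold to obtain VTA volumes that
    grow with stimulation intensity.
    """
    if threshold_v_per_m2 < 0:
        raise InvalidParameterError("VTA threshold must be >= 0")
    mask = af.f_values > threshold_v_per_m2
    return VTAMask(grid=af.grid, mask=mask, threshold_v_per_m2=float(threshold_v_per_m2))
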