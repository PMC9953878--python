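"""Voxel-based Monte Carlo photon transport with VTA-gated fluorescence.

A single run couples two wavelengths: 465 nm excitation packets are
launched from the optical fiber, random-walk through the voxelized tissue
(hop-drop-spin), and wherever a fraction of packet weight dW is absorbed in
a voxel whose fluorescence quantum yield QY exceeds zero, an emission
packet of weight Wf = dW * QY is spawned isotropically and transported at
the 525 nm emission optics.  Emission packets do not re-fluoresce.

Per-interaction physics (weights are dimensionless, launched at 1):

    step        dS = -ln(xi) / (mu_a + mu_s)          (xi ~ U(0,1])
    deposit     dW = W * mu_a / (mu_a + mu_s);  W' = W - dW
    spin        Henyey-Greenstein deflection, uniform azimuth
    terminate   Russian roulette below a weight threshold; packets leaving
                the tissue cube are recorded as escaped (index-matched
                boundary, no Fresnel reflection)

Per-voxel fluence is recovered from accumulated absorbed weight as

    phi = W_absorbed / (mu_a * V)        [weight / cm^2]

with V the voxel volume in cm^3.  The summed emission-wavelength fluence is
the simulated calcium-fluorescence intensity read out by the pipeline.

The transport loop is numba-compiled; a fixed seed gives bit-identical
fluence maps on a given platform.  Scalar single-interaction operations
(:func:`sample_step`, :func:`absorb`, ...) are also exposed in plain Python
for inspection and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .grid import InvalidParameterError, OpticalProperties, VoxelGrid

#: Default Russian-roulette weight threshold and survival probability
#: (standard MCML practice; the source description leaves termination open).
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass
class PhotonPacket:
    """Monte Carlo photon-packet state."""

    position_um: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    wavelength_tag: str = "excitation"
    alive: bool = True


@dataclass(frozen=True)
class FiberSpec:
    """Multimode optical fiber launching a defocused, uniform beam.

    The source is uniform over the fiber core disc (200 um diameter) and
    uniform in solid angle within a cone of ``half_angle_deg`` about the
    fiber axis.  The default 20.5 deg launch half-angle corresponds to the
    0.48 NA core in tissue of refractive index ~1.37.
    """

    tip_position_um: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    core_diameter_um: float = 200.0
    numerical_aperture: float = 0.48
    half_angle_deg: float = 20.5

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0:
            raise InvalidParameterError("fiber core diameter must be positive")
        if not (0.0 < self.numerical_aperture):
            raise InvalidParameterError("numerical aperture must be positive")
        if not (0.0 <= self.half_angle_deg < 90.0):
            raise InvalidParameterError("launch half-angle must be in [0, 90) deg")
        norm = float(np.linalg.norm(self.axis))
        if norm == 0:
            raise InvalidParameterError("fiber axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(float(a) / norm for a in self.axis))

    @classmethod
    def from_na(cls, tip_position_um, axis=(0.0, 0.0, 1.0), core_diameter_um=200.0,
                numerical_aperture=0.48, tissue_n=1.37) -> "FiberSpec":
        """Derive the launch half-angle as asin(NA / n_tissue)."""
        half = math.degrees(math.asin(numerical_aperture / tissue_n))
        return cls(tip_position_um=tip_position_um, axis=axis,
                   core_diameter_um=core_diameter_um,
                   numerical_aperture=numerical_aperture, half_angle_deg=half)


@dataclass(frozen=True)
class FluorophoreMap:
    """Per-voxel fluorescence quantum yield in [0, 1].

    In the pipeline QY is 1 inside the VTA (normal indicator expression in
    the activated region) and 0 outside.
    """

    grid: VoxelGrid
    qy: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.qy < 0) or np.any(self.qy > 1):
            raise InvalidParameterError("quantum yield must lie in [0, 1]")


@dataclass
class FluenceMap:
    """Accumulated absorbed weight and derived fluence for one wavelength."""

    grid: VoxelGrid
    absorbed_weight: np.ndarray
    wavelength_tag: str
    launched_weight: float
    escaped_weight: float
    roulette_net: float  # killed minus injected weight; exact conservation ledger
    phi: np.ndarray | None = None

    @property
    def total_absorbed(self) -> float:
        return float(self.absorbed_weight.sum())

    @property
    def escaped_fraction(self) -> float:
        if self.launched_weight == 0:
            return 0.0
        return self.escaped_weight / self.launched_weight

    @property
    def total_phi(self) -> float:
        if self.phi is None:
            raise InvalidParameterError("fluence not yet computed; call fluence_from_absorption")
        return float(self.phi.sum())

    def conservation_error(self) -> float:
        """|launched - absorbed - escaped - roulette_net| / launched."""
        if self.launched_weight == 0:
            return 0.0
        return abs(self.launched_weight - self.total_absorbed - self.escaped_weight
                   - self.roulette_net) / self.launched_weight


# ---------------------------------------------------------------------------
# Scalar single-interaction operations (plain Python, used in tests/examples)
# ---------------------------------------------------------------------------

def sample_step(xi: float, props: OpticalProperties) -> float:
    """Free-path step length dS = -ln(xi)/(mu_a + mu_s), in cm."""
    if not (0.0 < xi <= 1.0):
        raise InvalidParameterError("step variate xi must lie in (0, 1]")
    return -math.log(xi) / props.mu_t_per_cm


def absorb(packet: PhotonPacket, props: OpticalProperties) -> tuple[float, PhotonPacket]:
    """Deposit dW = W * mu_a/(mu_a+mu_s); return (dW, updated packet)."""
    if not packet.alive:
        raise InvalidParameterError("cannot absorb into a terminated packet")
    dw = packet.weight * props.mu_a_per_cm / props.mu_t_per_cm
    return dw, replace(packet, weight=packet.weight - dw)


def emit_fluorescence(delta_w: float, qy: float) -> float:
    """Initial emission-packet weight Wf = dW * QY."""
    if not (0.0 <= qy <= 1.0):
        raise InvalidParameterError("quantum yield must lie in [0, 1]")
    return delta_w * qy


def scatter_direction(direction, g: float, rng: np.random.Generator) -> np.ndarray:
    """Henyey-Greenstein deflection of a unit direction vector."""
    if not (-1.0 < g < 1.0):
        raise InvalidParameterError("anisotropy g must be in (-1, 1)")
    u = rng.random()
    if abs(g) < 1e-12:
        cost = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * rng.random()
    return _rotate(np.asarray(direction, dtype=float), cost, sint, phi)


def _rotate(d: np.ndarray, cost: float, sint: float, phi: float) -> np.ndarray:
    ux, uy, uz = d
    cosp, sinp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        out = np.array([sint * cosp, sint * sinp, cost if uz > 0 else -cost])
    else:
        den = math.sqrt(1.0 - uz * uz)
        out = np.array([
            sint * (ux * uz * cosp - uy * sinp) / den + ux * cost,
            sint * (uy * uz * cosp + ux * sinp) / den + uy * cost,
            -sint * cosp * den + uz * cost,
        ])
    return out / np.linalg.norm(out)


def _fiber_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(axis, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def launch_from_fiber(fiber: FiberSpec, rng: np.random.Generator) -> PhotonPacket:
    """Sample one excitation packet from the fiber launch distribution."""
    axis = np.asarray(fiber.axis, dtype=float)
    e1, e2 = _fiber_basis(axis)
    r = fiber.core_diameter_um / 2.0 * math.sqrt(rng.random())
    ang = 2.0 * math.pi * rng.random()
    pos = np.asarray(fiber.tip_position_um, dtype=float) + r * (
        math.cos(ang) * e1 + math.sin(ang) * e2)
    cos_half = math.cos(math.radians(fiber.half_angle_deg))
    cost = 1.0 - rng.random() * (1.0 - cos_half)  # uniform in solid angle
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    psi = 2.0 * math.pi * rng.random()
    direction = cost * axis + sint * (math.cos(psi) * e1 + math.sin(psi) * e2)
    direction /= np.linalg.norm(direction)
    return PhotonPacket(position_um=pos, direction=direction, weight=1.0,
                        wavelength_tag="excitation", alive=True)


def fluence_from_absorption(fmap: FluenceMap, props: OpticalProperties,
                            grid: VoxelGrid | None = None) -> FluenceMap:
    """Fill per-voxel fluence phi = absorbed / (mu_a * V) on a fluence map."""
    if props.mu_a_per_cm <= 0:
        raise InvalidParameterError("fluence undefined for mu_a = 0")
    g = grid if grid is not None else fmap.grid
    fmap.phi = fmap.absorbed_weight / (props.mu_a_per_cm * g.voxel_volume_cm3)
    return fmap


# ---------------------------------------------------------------------------
# Compiled transport kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hg_cost(g: float) -> float:
    u = np.random.random()
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, cost):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * np.random.random()
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz > 0 else -cost
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _transport_one(x, y, z, ux, uy, uz, w, mu_a, mu_s, g,
                   absorbed, ox, oy, oz, edge, nx, ny, nz,
                   w_threshold, p_survive):
    """Transport a single packet to termination; returns (escaped, roulette_net)."""
    mu_t = mu_a + mu_s
    inv_mu_t_um = 1e4 / mu_t  # mean free path in um
    escaped = 0.0
    roulette_net = 0.0
    while True:
        step = -math.log(np.random.random()) * inv_mu_t_um
        x += ux * step
        y += uy * step
        z += uz * step
        i = int(math.floor((x - ox) / edge))
        j = int(math.floor((y - oy) / edge))
        k = int(math.floor((z - oz) / edge))
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            escaped += w
            return escaped, roulette_net
        dw = w * mu_a / mu_t
        absorbed[i, j, k] += dw
        w -= dw
        if w < w_threshold:
            if np.random.random() < p_survive:
                boost = w / p_survive - w
                roulette_net -= boost
                w += boost
            else:
                roulette_net += w
                return escaped, roulette_net
        cost = _hg_cost(g)
        ux, uy, uz = _spin(ux, uy, uz, cost)


@njit(cache=True)
def _run_kernel(n_photons, seed,
                tipx, tipy, tipz, ax, ay, az, e1x, e1y, e1z, e2x, e2y, e2z,
                core_radius, cos_half,
                mu_a_ex, mu_s_ex, g_ex, mu_a_em, mu_s_em, g_em,
                qy, absorbed_ex, absorbed_em,
                ox, oy, oz, edge, nx, ny, nz,
                w_threshold, p_survive):
    """Excitation transport with inline VTA-gated fluorescence spawning.

    Returns (escaped_ex, roulette_ex, launched_em, escaped_em, roulette_em).
    """
    np.random.seed(seed)
    mu_t = mu_a_ex + mu_s_ex
    inv_mu_t_um = 1e4 / mu_t
    escaped_ex = 0.0
    roulette_ex = 0.0
    launched_em = 0.0
    escaped_em = 0.0
    roulette_em = 0.0
    for _ in range(n_photons):
        # launch: uniform disc, uniform solid angle in cone
        r = core_radius * math.sqrt(np.random.random())
        ang = 2.0 * math.pi * np.random.random()
        ca = math.cos(ang)
        sa = math.sin(ang)
        x = tipx + r * (ca * e1x + sa * e2x)
        y = tipy + r * (ca * e1y + sa * e2y)
        z = tipz + r * (ca * e1z + sa * e2z)
        cost = 1.0 - np.random.random() * (1.0 - cos_half)
        sint = math.sqrt(max(0.0, 1.0 - cost * cost))
        psi = 2.0 * math.pi * np.random.random()
        cp = math.cos(psi)
        sp = math.sin(psi)
        ux = cost * ax + sint * (cp * e1x + sp * e2x)
        uy = cost * ay + sint * (cp * e1y + sp * e2y)
        uz = cost * az + sint * (cp * e1z + sp * e2z)
        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= norm
        uy /= norm
        uz /= norm
        w = 1.0
        while True:
            step = -math.log(np.random.random()) * inv_mu_t_um
            x += ux * step
            y += uy * step
            z += uz * step
            i = int(math.floor((x - ox) / edge))
            j = int(math.floor((y - oy) / edge))
            k = int(math.floor((z - oz) / edge))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped_ex += w
                break
            dw = w * mu_a_ex / mu_t
            absorbed_ex[i, j, k] += dw
            w -= dw
            q = qy[i, j, k]
            if q > 0.0 and dw > 0.0:
                wf = dw * q
                launched_em += wf
                # isotropic emission from the absorption point
                ecost = 2.0 * np.random.random() - 1.0
                esint = math.sqrt(max(0.0, 1.0 - ecost * ecost))
                ephi = 2.0 * math.pi * np.random.random()
                eux = esint * math.cos(ephi)
                euy = esint * math.sin(ephi)
                euz = ecost
                esc, rnet = _transport_one(x, y, z, eux, euy, euz, wf,
                                           mu_a_em, mu_s_em, g_em, absorbed_em,
                                           ox, oy, oz, edge, nx, ny, nz,
                                           w_threshold, p_survive)
                escaped_em += esc
                roulette_em += rnet
            if w < w_threshold:
                if np.random.random() < p_survive:
                    boost = w / p_survive - w
                    roulette_ex -= boost
                    w += boost
                else:
                    roulette_ex += w
                    break
            cost = _hg_cost(g_ex)
            ux, uy, uz = _spin(ux, uy, uz, cost)
    return escaped_ex, roulette_ex, launched_em, escaped_em, roulette_em


def run_excitation_emission(grid: VoxelGrid, props_excitation: OpticalProperties,
                            props_emission: OpticalProperties, fiber: FiberSpec,
                            qy_map: FluorophoreMap, n_photons: int, seed: int,
                            roulette_threshold: float = ROULETTE_THRESHOLD,
                            roulette_survival: float = ROULETTE_SURVIVAL,
                            ) -> tuple[FluenceMap, FluenceMap, float]:
    """Full coupled excitation + emission transport run.

    Returns ``(excitation_fluence, emission_fluence, total_phi_emission)``
    where the scalar is the summed per-voxel emission fluence — the
    simulated calcium-fluorescence intensity for this stimulation condition.
    """
    if n_photons < 1:
        raise InvalidParameterError("n_photons must be >= 1")
    if not grid.contains(fiber.tip_position_um):
        raise InvalidParameterError("fiber tip must lie inside the grid")
    if qy_map.qy.shape != grid.shape:
        raise InvalidParameterError("quantum-yield map shape must match the grid")

    axis = np.asarray(fiber.axis, dtype=float)
    e1, e2 = _fiber_basis(axis)
    absorbed_ex = np.zeros(grid.shape, dtype=np.float64)
    absorbed_em = np.zeros(grid.shape, dtype=np.float64)
    qy = np.ascontiguousarray(qy_map.qy, dtype=np.float64)

    (escaped_ex, roulette_ex, launched_em, escaped_em, roulette_em) = _run_kernel(
        int(n_photons), int(seed) & 0x7FFFFFFF,
        *[float(v) for v in fiber.tip_position_um],
        float(axis[0]), float(axis[1]), float(axis[2]),
        float(e1[0]), float(e1[1]), float(e1[2]),
        float(e2[0]), float(e2[1]), float(e2[2]),
        fiber.core_diameter_um / 2.0, math.cos(math.radians(fiber.half_angle_deg)),
        props_excitation.mu_a_per_cm, props_excitation.mu_s_per_cm, props_excitation.g,
        props_emission.mu_a_per_cm, props_emission.mu_s_per_cm, props_emission.g,
        qy, absorbed_ex, absorbed_em,
        float(grid.origin_um[0]), float(grid.origin_um[1]), float(grid.origin_um[2]),
        float(grid.voxel_edge_um), *grid.shape,
        float(roulette_threshold), float(roulette_survival))

    fmap_ex = FluenceMap(grid=grid, absorbed_weight=absorbed_ex,
                         wavelength_tag="excitation", launched_weight=float(n_photons),
                         escaped_weight=escaped_ex, roulette_net=roulette_ex)
    fmap_em = FluenceMap(grid=grid, absorbed_weight=absorbed_em,
                         wavelength_tag="emission", launched_weight=launched_em,
                         escaped_weight=escaped_em, roulette_net=roulette_em)
    fluence_from_absorption(fmap_ex, props_excitation)
    fluence_from_absorption(fmap_em, props_emission)
    return fmap_ex, fmap_em, fmap_em.total_phi
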