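"""Voxelized tissue volume shared by the field and photon-transport modules.

The simulation domain is an axis-aligned cube of homogeneous brain tissue
(default 2 x 2 x 2 mm) discretized into cubic voxels (default 10 um edge).
All volumetric maps — extracellular potential, activating function,
fluorescence quantum yield, absorbed photon weight, fluence — live on the
same :class:`VoxelGrid` so that the electrical and optical chains compose
voxel-for-voxel.

Coordinates are physical micrometres with the grid corner (the corner of
voxel ``(0, 0, 0)``) at ``origin_um``.  Voxels are half-open intervals
``[low, high)`` along each axis so that no point belongs to two voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidParameterError(ValueError):
    """A configuration value violates its domain constraint."""


class OutsideGridError(Exception):
    """A physical point falls outside the grid extent.

    The photon-transport loop relies on this condition to detect escape
    through the tissue-cube faces.
    """


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned cubic-voxel lattice.

    Parameters
    ----------
    shape:
        Number of voxels along (x, y, z); each component >= 1.
    voxel_edge_um:
        Edge length of a voxel in micrometres (> 0).
    origin_um:
        Physical coordinate of the low corner of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_edge_um: float = 10.0
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_edge_um <= 0:
            raise InvalidParameterError("voxel edge must be positive")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise InvalidParameterError("grid shape must be three integers >= 1")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin_um", tuple(float(v) for v in self.origin_um))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis, exactly shape * edge."""
        return tuple(n * self.voxel_edge_um for n in self.shape)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(e / 1000.0 for e in self.extent_um)

    @property
    def voxel_volume_cm3(self) -> float:
        """Voxel volume in cm^3 (1e-9 cm^3 for the default 10 um edge)."""
        edge_cm = self.voxel_edge_um * 1e-4
        return edge_cm**3

    @property
    def voxel_volume_mm3(self) -> float:
        edge_mm = self.voxel_edge_um * 1e-3
        return edge_mm**3

    def contains(self, point_um) -> bool:
        p = np.asarray(point_um, dtype=float)
        lo = np.asarray(self.origin_um)
        hi = lo + np.asarray(self.extent_um)
        return bool(np.all(p >= lo) and np.all(p < hi))

    def voxel_of(self, point_um) -> tuple[int, int, int]:
        """Voxel index containing a physical point (half-open intervals).

        Raises
        ------
        OutsideGridError
            If the point lies outside the grid extent.
        """
        if not self.contains(point_um):
            raise OutsideGridError(f"point {tuple(point_um)} outside grid extent")
        p = np.asarray(point_um, dtype=float) - np.asarray(self.origin_um)
        idx = np.floor(p / self.voxel_edge_um).astype(int)
        # floor can land on shape at the extreme float edge; clamp inward
        idx = np.minimum(idx, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def center_of(self, index) -> np.ndarray:
        """Physical coordinate (um) of the centre of voxel ``index``."""
        i = np.asarray(index, dtype=float)
        return np.asarray(self.origin_um) + (i + 0.5) * self.voxel_edge_um

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-centre coordinates (um)."""
        return tuple(
            self.origin_um[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_edge_um
            for a in range(3)
        )

    def meshgrid_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cx, cy, cz = self.centers()
        return np.meshgrid(cx, cy, cz, indexing="ij")


def make_grid(extent_mm=(2.0, 2.0, 2.0), voxel_edge_um: float = 10.0,
              origin_um=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Build a grid from a physical extent and voxel edge.

    The extent must be an integer number of voxels along each axis within
    rounding tolerance (1e-6 of a voxel).
    """
    if voxel_edge_um <= 0:
        raise InvalidParameterError("voxel edge must be positive")
    extent_mm = np.atleast_1d(np.asarray(extent_mm, dtype=float))
    if extent_mm.size == 1:
        extent_mm = np.repeat(extent_mm, 3)
    if np.any(extent_mm <= 0):
        raise InvalidParameterError("extent must be positive")
    n_f = extent_mm * 1000.0 / voxel_edge_um
    n = np.round(n_f).astype(int)
    if np.any(n < 1) or np.any(np.abs(n_f - n) > 1e-6 * np.maximum(n, 1)):
        raise InvalidParameterError(
            f"extent {tuple(extent_mm)} mm is not divisible by voxel edge "
            f"{voxel_edge_um} um"
        )
    return VoxelGrid(shape=tuple(int(v) for v in n), voxel_edge_um=float(voxel_edge_um),
                     origin_um=origin_um)


@dataclass(frozen=True)
class ElectricalMedium:
    """Bulk electrical properties of the tissue.

    ``conductivity_s_per_m`` is the in vivo conductivity K (default the
    measured 4.120 S/m).  The relative permittivity is carried as metadata
    only: at the quasi-static (DC) limit used for the stimulation field it
    plays no role.
    """

    conductivity_s_per_m: float = 4.120
    relative_permittivity: float = 80.0

    def __post_init__(self) -> None:
        if self.conductivity_s_per_m <= 0:
            raise InvalidParameterError("conductivity must be positive")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength tissue optics for the Monte Carlo transport.

    mu_a and mu_s are the absorption and scattering coefficients in 1/cm.
    ``g`` is the Henyey-Greenstein scattering anisotropy and ``n`` the
    tissue refractive index; neither is printed alongside the measured
    coefficients, so they default to typical white-matter values (g = 0.9,
    n = 1.37 — note asin(0.48 / 1.37) ~ 20.5 deg, the fiber launch
    half-angle used throughout).
    """

    mu_a_per_cm: float
    mu_s_per_cm: float
    g: float = 0.9
    n: float = 1.37
    wavelength_tag: str = "excitation"

    def __post_init__(self) -> None:
        if self.mu_a_per_cm < 0 or self.mu_s_per_cm < 0:
            raise InvalidParameterError("mu_a and mu_s must be non-negative")
        if self.mu_a_per_cm + self.mu_s_per_cm <= 0:
            raise InvalidParameterError("mu_a + mu_s must be positive")
        if not (-1.0 < self.g < 1.0):
            raise InvalidParameterError("anisotropy g must be in (-1, 1)")
        if self.n < 1.0:
            raise InvalidParameterError("refractive index must be >= 1")
        if self.wavelength_tag not in ("excitation", "emission"):
            raise InvalidParameterError("wavelength_tag must be excitation|emission")

    @property
    def mu_t_per_cm(self) -> float:
        """Total attenuation coefficient mu_a + mu_s."""
        return self.mu_a_per_cm + self.mu_s_per_cm

    @property
    def albedo(self) -> float:
        """Per-interaction survival fraction mu_s / (mu_a + mu_s)."""
        return self.mu_s_per_cm / self.mu_t_per_cm


#: Measured white-matter optics at the 465 nm GCaMP excitation wavelength.
EXCITATION_465 = OpticalProperties(4.642, 257.631, wavelength_tag="excitation")
#: Measured white-matter optics at the 525 nm emission wavelength.
EMISSION_525 = OpticalProperties(4.873, 224.074, wavelength_tag="emission")
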