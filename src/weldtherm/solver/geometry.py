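"""Voxel weld geometry: tissue slab clamped between two electrode blocks.

Axes: x spans the heat-spread direction (x = 0 at the slab centre), y the
slab width, z the thickness. Cell-centred coordinates, 0-based indices.
The z stacking is lower electrode | tissue | upper electrode; electrode
layers exist only over the footprint columns, the rest is void (air).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["Region", "GeometryConfig", "GeometryError", "WeldGeometry", "build_geometry"]


class GeometryError(ValueError):
    """Inconsistent geometry request (e.g. footprint wider than the slab)."""


class Region(IntEnum):
    VOID = 0
    TISSUE = 1
    UPPER_ELECTRODE = 2
    LOWER_ELECTRODE = 3


REGION_NAMES = {
    Region.TISSUE: "tissue",
    Region.UPPER_ELECTRODE: "upper_electrode",
    Region.LOWER_ELECTRODE: "lower_electrode",
}


@dataclass(frozen=True)
class GeometryConfig:
    """Physical extents (m) and target spacings (m) of the weld setup."""

    slab_length_x: float = 20e-3
    slab_width_y: float = 10e-3
    tissue_thickness: float = 0.958e-3
    electrode_footprint: float = 3e-3
    electrode_thickness: float = 1.75e-3
    dx: float = 0.2e-3
    dy: float = 0.2e-3
    dz_target: float = 0.12e-3
    dz_electrode_target: float = 0.875e-3

    def __post_init__(self) -> None:
        for name in (
            "slab_length_x",
            "slab_width_y",
            "tissue_thickness",
            "electrode_footprint",
            "electrode_thickness",
            "dx",
            "dy",
            "dz_target",
            "dz_electrode_target",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.electrode_footprint > self.slab_length_x + 1e-12:
            raise GeometryError(
                "electrode footprint exceeds the tissue slab along x "
                f"({self.electrode_footprint} > {self.slab_length_x})"
            )


@dataclass(frozen=True)
class WeldGeometry:
    """Labelled voxel grid with probe regions and cell-centred coordinates."""

    config: GeometryConfig
    nx: int
    ny: int
    nz_tissue: int
    nz_electrode: int
    dx: float
    dy: float
    dz: float  # tissue layer thickness
    dz_electrode: float  # electrode layer thickness
    labels: np.ndarray  # (nx, ny, nz) int8 of Region codes
    ix_lo: int  # first footprint column (inclusive)
    ix_hi: int  # last footprint column (exclusive)

    @property
    def nz(self) -> int:
        return self.labels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx - self.nx * self.dx / 2.0

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy - self.ny * self.dy / 2.0

    @property
    def dz_layers(self) -> np.ndarray:
        """Per-z-layer thickness (m): coarse copper layers, fine tissue layers."""
        return np.concatenate(
            [
                np.full(self.nz_electrode, self.dz_electrode),
                np.full(self.nz_tissue, self.dz),
                np.full(self.nz_electrode, self.dz_electrode),
            ]
        )

    @property
    def z_centers(self) -> np.ndarray:
        dz = self.dz_layers
        return np.cumsum(dz) - dz / 2.0

    @property
    def tissue_z(self) -> slice:
        return slice(self.nz_electrode, self.nz_electrode + self.nz_tissue)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels == Region.TISSUE

    @property
    def active_mask(self) -> np.ndarray:
        return self.labels != Region.VOID

    @property
    def central_mask(self) -> np.ndarray:
        """Tissue cells under the electrode footprint (covered, IR-invisible)."""
        m = np.zeros(self.shape, dtype=bool)
        m[self.ix_lo : self.ix_hi, :, self.tissue_z] = True
        return m & self.tissue_mask

    @property
    def edge_mask(self) -> np.ndarray:
        """Exposed tissue cells beside the footprint (IR-visible)."""
        return self.tissue_mask & ~self.central_mask

    @property
    def edge_x(self) -> float:
        """x coordinate (m) of the positive-side electrode edge."""
        return self.x_centers[self.ix_hi - 1] + self.dx / 2.0

    @property
    def cell_volumes(self) -> np.ndarray:
        """Per-z-layer cell volume (m^3)."""
        return self.dx * self.dy * self.dz_layers

    def volume_flat(self) -> np.ndarray:
        """Cell volume for every flat (C-order) grid index."""
        return np.broadcast_to(self.cell_volumes, self.shape).ravel()

    def region_name(self, code: int) -> str:
        return REGION_NAMES[Region(code)]


def build_geometry(config: GeometryConfig | None = None) -> WeldGeometry:
    """Build the labelled voxel grid for a geometry config.

    Cell counts are rounded from the physical extents; dz is adjusted so the
    tissue thickness is represented exactly by an integer number of layers.
    """
    config = config or GeometryConfig()
    nx = max(1, round(config.slab_length_x / config.dx))
    ny = max(1, round(config.slab_width_y / config.dy))
    nz_t = max(1, round(config.tissue_thickness / config.dz_target))
    dz = config.tissue_thickness / nz_t
    nz_e = max(1, round(config.electrode_thickness / config.dz_electrode_target))
    dz_e = config.electrode_thickness / nz_e
    nz = nz_t + 2 * nz_e

    n_fp = round(config.electrode_footprint / config.dx)
    n_fp = min(max(n_fp, 1), nx)
    ix_lo = (nx - n_fp) // 2
    ix_hi = ix_lo + n_fp

    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    labels[:, :, nz_e : nz_e + nz_t] = Region.TISSUE
    labels[ix_lo:ix_hi, :, :nz_e] = Region.LOWER_ELECTRODE
    labels[ix_lo:ix_hi, :, nz_e + nz_t :] = Region.UPPER_ELECTRODE

    return WeldGeometry(
        config=config,
        nx=nx,
        ny=ny,
        nz_tissue=nz_t,
        nz_electrode=nz_e,
        dx=config.dx,
        dy=config.dy,
        dz=dz,
        dz_electrode=dz_e,
        labels=labels,
        ix_lo=ix_lo,
        ix_hi=ix_hi,
    )
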