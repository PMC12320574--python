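"""Multicellular cluster geometry.

A spheroid is modeled as a simple-cubic lattice of identical spherical cells
(nucleus concentric with the cell).  The lattice extends beyond the spheroid
radius out to a larger cluster radius; the surrounding shell of lattice sites
represents culture medium and can carry activity just like cells, so that
dose from radioactivity in the medium is computed with the same machinery.

One lattice site sits exactly at the origin, so a center cell always exists
for dose-depth profiles.  A site belongs to the cluster (and to the spheroid)
iff its *center* lies within the respective radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpheroidConfig", "CellLattice", "build_cluster", "radial_shells"]


@dataclass(frozen=True)
class SpheroidConfig:
    """Geometric parameters of the cell cluster (all lengths in um).

    Defaults are BT474-like spheroids: 6-um cells with 3-um nuclei on a
    12-um simple-cubic lattice, a 200-um spheroid inside a 350-um cluster
    whose outer 150-um shell of sites represents medium.
    """

    cell_radius: float = 6.0
    nucleus_radius: float = 3.0
    lattice_spacing: float = 12.0
    spheroid_radius: float = 200.0
    cluster_radius: float = 350.0
    shell_width: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.nucleus_radius < self.cell_radius):
            raise ValueError("need 0 < nucleus_radius < cell_radius")
        if self.cell_radius > self.lattice_spacing / 2:
            raise ValueError("cells overlap: cell_radius > lattice_spacing/2")
        if self.spheroid_radius > self.cluster_radius:
            raise ValueError("spheroid_radius exceeds cluster_radius")
        if self.shell_width <= 0:
            raise ValueError("shell_width must be positive")

    @property
    def site_volume_um3(self) -> float:
        """Volume of one lattice site (the per-cell medium volume)."""
        return self.lattice_spacing**3


@dataclass
class CellLattice:
    """Positions and region labels of all lattice sites in a cluster.

    Attributes
    ----------
    centers : (N, 3) float array of site centers in um.
    ijk : (N, 3) int array of lattice indices (origin site = (0, 0, 0)).
    radial_distance : (N,) distances from the cluster center in um.
    region : (N,) strings, "spheroid" or "medium".
    shell_index : (N,) index of the concentric radial shell holding each site.
    """

    config: SpheroidConfig
    centers: np.ndarray
    ijk: np.ndarray
    radial_distance: np.ndarray
    region: np.ndarray
    shell_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shell_index is None:
            self.shell_index = radial_shells(self, self.config.shell_width)

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def spheroid_mask(self) -> np.ndarray:
        return self.region == "spheroid"

    @property
    def medium_mask(self) -> np.ndarray:
        return self.region == "medium"

    # -- dense-grid helpers used by the FFT dose convolution ---------------
    @property
    def grid_halfwidth(self) -> int:
        return int(np.max(np.abs(self.ijk)))

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-cell vector onto a dense cubic grid (zeros elsewhere)."""
        n = self.grid_halfwidth
        grid = np.zeros((2 * n + 1,) * 3, dtype=float)
        idx = self.ijk + n
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = values
        return grid

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        """Gather per-cell values back from a dense cubic grid."""
        n = self.grid_halfwidth
        idx = self.ijk + n
        return grid[idx[:, 0], idx[:, 1], idx[:, 2]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
                "z_um": self.centers[:, 2],
                "region": self.region,
                "radius_um": self.radial_distance,
                "shell_index": self.shell_index,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_cluster(config: SpheroidConfig) -> CellLattice:
    """Construct the origin-anchored simple-cubic cluster for `config`.

    All lattice sites whose centers lie within ``cluster_radius`` are
    included; sites within ``spheroid_radius`` are labeled "spheroid" and
    the rest "medium".
    """
    s = config.lattice_spacing
    nmax = int(np.floor(config.cluster_radius / s))
    ax = np.arange(-nmax, nmax + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    # exact integer membership test: s^2*(i^2+j^2+k^2) <= R^2
    q = np.sum(ijk.astype(np.int64) ** 2, axis=1)
    inside = q * s * s <= config.cluster_radius**2
    ijk = ijk[inside]
    centers = ijk * s
    dist = s * np.sqrt(q[inside].astype(float))
    region = np.where(dist * dist <= config.spheroid_radius**2, "spheroid", "medium")
    lat = CellLattice(
        config=config,
        centers=centers.astype(float),
        ijk=ijk.astype(int),
        radial_distance=dist,
        region=region,
        shell_index=np.floor(dist / config.shell_width).astype(int),
    )
    return lat


def radial_shells(lattice: CellLattice, width: float) -> np.ndarray:
    """Assign each cell to the concentric shell ``floor(r / width)``.

    Shells partition the cluster; shell k covers radii [k*width, (k+1)*width).
    """
    if width <= 0:
        raise ValueError("shell width must be positive")
    return np.floor(lattice.radial_distance / width).astype(int)
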