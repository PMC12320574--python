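"""Cellular S-coefficients for alpha emitters.

The absorbed dose to a cell nucleus per radioactive decay (the cellular
S-coefficient) is computed in the continuous-slowing-down approximation:
alpha particles travel on straight tracks, losing energy according to a
bundled range-energy table for liquid water, and the energy deposited in a
target nucleus is the difference of the residual energies at the entry and
exit points of the track's chord through the nucleus.  Sources are
distributed over a cell compartment (cell surface, cytoplasm, or nucleus)
with isotropic emission; targets are the 3-um nuclei of the same cell
(self-dose) or of neighboring cells (cross-dose).

Only alpha emissions are transported.  The Ac-225 chain can be loaded either
as the parent alone (one alpha group) or with its short-lived daughters
(Fr-221, At-217, Bi-213/Po-213) in secular equilibrium, which adds three
more alpha groups for a total alpha yield of ~4 per parent decay.  Beta and
photon components are neglected: at cellular distances the alpha self- and
cross-dose dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .geometry import SpheroidConfig
from .units import MEV_TO_J, sphere_mass_kg

__all__ = [
    "EmissionSpectrum",
    "RangeEnergyTable",
    "SValueKernel",
    "load_decay_chain",
    "load_range_energy_table",
    "self_svalue",
    "cross_svalue",
    "daughter_correction_factor",
    "build_kernel",
    "point_source_nucleus_dose",
]

COMPARTMENTS = ("cell_surface", "cytoplasm", "nucleus")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Alpha emission lines of a nuclide or decay chain.

    ``lines`` is a sequence of (energy [MeV], yield [alphas per parent
    decay]) pairs.  A parent-only spectrum has total yield ~1; the Ac-225
    chain in equilibrium has total yield ~4.
    """

    lines: tuple[tuple[float, float], ...]
    chain_name: str = ""
    includes_daughters: bool = False

    def __post_init__(self) -> None:
        if len(self.lines) == 0:
            raise ValueError("emission spectrum has no lines")
        for e, y in self.lines:
            if e <= 0:
                raise ValueError("alpha energies must be positive")
            if not (0 < y <= 4):
                raise ValueError("yields must lie in (0, 4]")

    @property
    def total_yield(self) -> float:
        return float(sum(y for _, y in self.lines))

    @property
    def total_energy_mev(self) -> float:
        """Total alpha energy emitted per parent decay."""
        return float(sum(e * y for e, y in self.lines))

    @property
    def max_energy_mev(self) -> float:
        return float(max(e for e, _ in self.lines))


class RangeEnergyTable:
    """Monotone CSDA range-energy relation for alphas in water.

    Interpolates in both directions with shape-preserving (PCHIP) splines so
    that range(E) is strictly increasing and energy(range(E)) round-trips.
    """

    def __init__(self, energies_mev: np.ndarray, ranges_um: np.ndarray):
        energies_mev = np.asarray(energies_mev, dtype=float)
        ranges_um = np.asarray(ranges_um, dtype=float)
        if energies_mev.ndim != 1 or energies_mev.shape != ranges_um.shape:
            raise ValueError("energies and ranges must be matching 1-D arrays")
        if np.any(np.diff(energies_mev) <= 0) or np.any(np.diff(ranges_um) <= 0):
            raise ValueError("range-energy table must be strictly increasing")
        if energies_mev[0] != 0 or ranges_um[0] != 0:
            raise ValueError("table must start at (0, 0)")
        self.energies_mev = energies_mev
        self.ranges_um = ranges_um
        self._r_of_e = PchipInterpolator(energies_mev, ranges_um)
        # build the inverse from a dense resampling of the forward curve so
        # that energy(range(E)) round-trips to interpolation precision
        e_dense = np.linspace(0.0, energies_mev[-1], 4001)
        self._e_of_r = PchipInterpolator(self._r_of_e(e_dense), e_dense)

    @classmethod
    def from_file(cls, path) -> "RangeEnergyTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["energy_mev"].to_numpy(), df["range_um"].to_numpy())

    @property
    def max_energy_mev(self) -> float:
        return float(self.energies_mev[-1])

    def range(self, energy_mev) -> np.ndarray:
        """CSDA range in um at the given alpha energy (MeV)."""
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < 0) or np.any(e > self.max_energy_mev):
            raise ValueError("energy outside table domain")
        return self._r_of_e(e)

    def energy(self, range_um) -> np.ndarray:
        """Inverse relation: energy (MeV) of an alpha with the given residual range."""
        r = np.asarray(range_um, dtype=float)
        if np.any(r < 0) or np.any(r > self.ranges_um[-1]):
            raise ValueError("range outside table domain")
        return self._e_of_r(r)

    def energy_clipped(self, range_um) -> np.ndarray:
        """energy() with ranges clipped into the table domain (for track ends)."""
        r = np.clip(np.asarray(range_um, dtype=float), 0.0, self.ranges_um[-1])
        return self._e_of_r(r)


def _data_path(name: str):
    return resources.files("spheradose.data").joinpath(name)


def load_range_energy_table() -> RangeEnergyTable:
    """The bundled alpha range-energy table for liquid water."""
    return RangeEnergyTable.from_file(_data_path("alpha_range_water.tsv"))


def load_decay_chain(chain_name: str = "Ac-225",
                     include_daughters: bool = True) -> EmissionSpectrum:
    """Load the alpha spectrum of a decay chain from the bundled nuclear data.

    With ``include_daughters=False`` only the parent alpha group is returned;
    otherwise the daughters are added at secular-equilibrium yields.
    """
    if chain_name != "Ac-225":
        raise ValueError(f"unknown decay chain: {chain_name!r}")
    df = pd.read_csv(_data_path("ac225_alpha_lines.tsv"), sep="\t", comment="#")
    if not include_daughters:
        df = df[df["role"] == "parent"]
    lines = tuple((float(e), float(y)) for e, y in zip(df["energy_mev"], df["yield"]))
    return EmissionSpectrum(lines=lines, chain_name=chain_name,
                            includes_daughters=include_daughters)


# ---------------------------------------------------------------------------
# track integration
# ---------------------------------------------------------------------------

def point_source_nucleus_dose(distances_um, spectrum: EmissionSpectrum,
                              nucleus_radius: float,
                              table: RangeEnergyTable | None = None,
                              n_mu: int = 2001) -> np.ndarray:
    """Mean dose (Gy) to a spherical nucleus per decay of an isotropic point source.

    The source sits at center-to-center distance d (which may be inside the
    nucleus, d < nucleus_radius).  For each emission direction the energy
    deposited is the residual-energy difference across the chord through the
    nucleus; the direction average reduces to a 1-D integral over the cosine
    of the angle to the source-center axis, evaluated by the trapezoid rule
    on ``n_mu`` nodes.
    """
    if table is None:
        table = load_range_energy_table()
    d = np.atleast_1d(np.asarray(distances_um, dtype=float))
    mu = np.linspace(-1.0, 1.0, n_mu)
    dep_mev = np.zeros((d.size, n_mu))
    dcol = d[:, None]
    for energy, yld in spectrum.lines:
        r0 = float(table.range(energy))
        disc = dcol * dcol * (mu * mu - 1.0) + nucleus_radius**2
        ok = disc > 0.0
        root = np.sqrt(np.where(ok, disc, 0.0))
        t1 = np.clip(dcol * mu - root, 0.0, r0)
        t2 = np.clip(dcol * mu + root, 0.0, r0)
        de = table.energy_clipped(r0 - t1) - table.energy_clipped(r0 - t2)
        dep_mev += yld * np.where(ok & (t2 > t1), de, 0.0)
    mean_mev = np.trapezoid(dep_mev, mu, axis=1) / 2.0
    dose = mean_mev * MEV_TO_J / sphere_mass_kg(nucleus_radius)
    return dose if np.ndim(distances_um) else float(dose[0])


class _PsvTable:
    """Fine-grained interpolation of the point-source nucleus dose vs distance."""

    def __init__(self, spectrum: EmissionSpectrum, nucleus_radius: float,
                 table: RangeEnergyTable, d_max: float, step: float = 0.1,
                 n_mu: int = 2001):
        self.d_max = float(d_max)
        grid = np.arange(0.0, d_max + step, step)
        vals = point_source_nucleus_dose(grid, spectrum, nucleus_radius, table,
                                         n_mu=n_mu)
        self._interp = PchipInterpolator(grid, vals)

    def __call__(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.zeros_like(d)
        inside = d < self.d_max
        out[inside] = np.clip(self._interp(d[inside]), 0.0, None)
        return out


def _compartment_average(psv, d, compartment: str, geometry: SpheroidConfig,
                         n_ang: int = 64, n_rad: int = 16) -> np.ndarray:
    """Average the point-source dose over a source compartment of a cell at
    center distance d from the target nucleus."""
    d = np.atleast_1d(np.asarray(d, dtype=float))
    x, wx = np.polynomial.legendre.leggauss(n_ang)  # cos(angle) on source sphere
    if compartment == "cell_surface":
        radii = np.array([geometry.cell_radius])
        wr = np.array([1.0])
    elif compartment == "cytoplasm":
        r, w = np.polynomial.legendre.leggauss(n_rad)
        a, b = geometry.nucleus_radius, geometry.cell_radius
        radii = 0.5 * (b - a) * r + 0.5 * (a + b)
        wr = w * radii**2
        wr = wr / wr.sum()
    elif compartment == "nucleus":
        r, w = np.polynomial.legendre.leggauss(n_rad)
        radii = 0.5 * geometry.nucleus_radius * (r + 1.0)
        wr = w * radii**2
        wr = wr / wr.sum()
    else:
        raise ValueError(f"unknown source compartment {compartment!r}")
    out = np.zeros_like(d)
    for rs, w_r in zip(radii, wr):
        dprime = np.sqrt(d[:, None] ** 2 + rs**2 - 2.0 * d[:, None] * rs * x)
        out += w_r * (psv(dprime) * wx).sum(axis=1) / 2.0
    return out


def self_svalue(compartment: str, geometry: SpheroidConfig,
                spectrum: EmissionSpectrum,
                table: RangeEnergyTable | None = None,
                n_mu: int = 2001, n_rad: int = 32) -> float:
    """Self-dose S-coefficient: mean dose to a cell's own nucleus per decay
    of activity distributed in the given compartment of that cell.

    Because the nucleus is concentric with the cell, a surface source reduces
    to a point source at distance cell_radius; volume compartments are
    averaged with Gauss-Legendre quadrature weighted by r^2.
    """
    if table is None:
        table = load_range_energy_table()
    rn = geometry.nucleus_radius
    if compartment == "cell_surface":
        return float(point_source_nucleus_dose(geometry.cell_radius, spectrum,
                                               rn, table, n_mu=n_mu))
    if compartment == "cytoplasm":
        a, b = rn, geometry.cell_radius
    elif compartment == "nucleus":
        a, b = 0.0, rn
    else:
        raise ValueError(f"unknown source compartment {compartment!r}")
    x, w = np.polynomial.legendre.leggauss(n_rad)
    radii = 0.5 * (b - a) * x + 0.5 * (a + b)
    wts = w * radii**2
    vals = point_source_nucleus_dose(radii, spectrum, rn, table, n_mu=n_mu)
    return float(np.sum(wts * vals) / np.sum(wts))


def daughter_correction_factor(geometry: SpheroidConfig | None = None,
                               compartment: str = "cell_surface",
                               table: RangeEnergyTable | None = None) -> float:
    """Ratio of full-chain to parent-only self-dose per parent decay.

    For the 6-um/3-um cell with a surface source this evaluates to ~3.5: the
    three daughter alphas deposit proportionally less per decay than a yield
    ratio of 4 would suggest because their longer ranges carry more energy
    out of the cell.
    """
    if geometry is None:
        geometry = SpheroidConfig()
    full = load_decay_chain("Ac-225", include_daughters=True)
    parent = load_decay_chain("Ac-225", include_daughters=False)
    s_full = self_svalue(compartment, geometry, full, table)
    s_parent = self_svalue(compartment, geometry, parent, table)
    return s_full / s_parent


def cross_svalue(distance_um, geometry: SpheroidConfig,
                 spectrum: EmissionSpectrum,
                 compartment: str = "cell_surface",
                 table: RangeEnergyTable | None = None,
                 psv: "_PsvTable | None" = None) -> np.ndarray:
    """Cross-dose S-coefficient: mean dose to a neighbor's nucleus at
    center-to-center distance d per decay in the source cell's compartment.

    The source is resolved at its compartment geometry for d <= 3 lattice
    spacings and treated as a point at the cell center beyond, where the
    finite source size is negligible.
    """
    if table is None:
        table = load_range_energy_table()
    d = np.atleast_1d(np.asarray(distance_um, dtype=float))
    max_reach = float(table.range(spectrum.max_energy_mev)) + \
        geometry.cell_radius + geometry.nucleus_radius
    if psv is None:
        psv = _PsvTable(spectrum, geometry.nucleus_radius, table,
                        d_max=max_reach + 2.0)
    near = d <= 3.0 * geometry.lattice_spacing
    out = np.zeros_like(d)
    if near.any():
        out[near] = _compartment_average(psv, d[near], compartment, geometry)
    if (~near).any():
        out[~near] = psv(d[~near])
    return out if np.ndim(distance_um) else float(out[0])


@dataclass
class SValueKernel:
    """Tabulated S-coefficients on the distinct distances of a cubic lattice.

    ``self_s`` maps each source compartment to the self-dose per decay;
    ``cross_distances``/``cross_values`` tabulate the cross-dose per decay at
    every lattice center-to-center distance up to the maximum alpha reach.
    """

    spacing: float
    compartment: str
    self_s: dict
    cross_distances: np.ndarray
    cross_values: np.ndarray
    max_range: float
    chain_name: str = ""
    includes_daughters: bool = False
    _grid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def cross(self, d) -> np.ndarray:
        """Cross-dose at arbitrary distances (zero beyond the alpha reach)."""
        d = np.asarray(d, dtype=float)
        out = np.zeros_like(d)
        ok = (d > 0) & (d <= self.cross_distances[-1])
        out[ok] = np.interp(d[ok], self.cross_distances, self.cross_values)
        return out

    def as_grid(self) -> np.ndarray:
        """Cross-dose kernel as a dense cubic array for lattice convolution.

        The center voxel is zero (self-dose is applied separately).
        """
        if self._grid is None:
            n = int(np.ceil(self.cross_distances[-1] / self.spacing))
            ax = np.arange(-n, n + 1)
            ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
            dist = self.spacing * np.sqrt(ii**2 + jj**2 + kk**2)
            grid = self.cross(dist)
            grid[n, n, n] = 0.0
            self._grid = grid
        return self._grid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_um": self.cross_distances,
                             "gy_per_decay": self.cross_values})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_kernel(config: SpheroidConfig, spectrum: EmissionSpectrum,
                 compartment: str = "cell_surface",
                 table: RangeEnergyTable | None = None) -> SValueKernel:
    """Build self- and cross-dose S-coefficients for a lattice of cells.

    Cross-dose values are tabulated on the distinct center-to-center
    distances of the simple-cubic lattice out to the maximum alpha reach
    (CSDA range of the most energetic line plus cell and nucleus radii).
    """
    if table is None:
        table = load_range_energy_table()
    max_range = float(table.range(spectrum.max_energy_mev))
    cutoff = max_range + config.cell_radius + config.nucleus_radius
    psv = _PsvTable(spectrum, config.nucleus_radius, table, d_max=cutoff + 2.0)

    s = config.lattice_spacing
    nmax = int(np.ceil(cutoff / s))
    ax = np.arange(0, nmax + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    q = np.unique(ii**2 + jj**2 + kk**2)
    q = q[q > 0]
    dists = s * np.sqrt(q.astype(float))
    dists = dists[dists <= cutoff]
    vals = cross_svalue(dists, config, spectrum, compartment, table, psv=psv)

    self_s = {
        comp: self_svalue(comp, config, spectrum, table) for comp in COMPARTMENTS
    }
    return SValueKernel(
        spacing=s,
        compartment=compartment,
        self_s=self_s,
        cross_distances=dists,
        cross_values=np.asarray(vals),
        max_range=max_range,
        chain_name=spectrum.chain_name,
        includes_daughters=spectrum.includes_daughters,
    )
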