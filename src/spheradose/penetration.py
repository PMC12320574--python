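"""From penetration measurements to time-integrated decays per cell.

Drug penetration into a spheroid is described by a spatiotemporal
concentration profile (arbitrary fluorescence-like units on a radial grid at
several time points during incubation).  This module converts such profiles
into the quantity the dosimetry needs: the cumulated number of decays per
cell at each radial depth, for the spheroid interior and for the surrounding
medium shell.

The conversion chain is

1. ``radial_profile_from_image`` - reduce a fluorescence image to mean
   intensity per concentric ring (the "eroding" reduction);
2. ``calibrate`` - rescale concentrations so that the medium plateau during
   incubation equals the applied activity concentration (the only absolute
   anchor available), multiply by the per-site volume and apply physical
   decay to obtain the per-cell activity over time;
3. ``time_integrate`` - trapezoidal integral over the incubation window plus
   an analytic tail for activity retained in the spheroid at washout, which
   is integrated to complete physical decay;
4. ``scale_amount`` / ``blend_profiles`` - rescale for activity
   apportionment and interpolate/extrapolate between measured profiles with
   and without preirradiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .units import (AC225_HALF_LIFE_DAYS, SECONDS_PER_HOUR,
                    decay_constant_per_s)

log = logging.getLogger(__name__)

__all__ = [
    "SpatioTemporalProfile",
    "CellActivityProfile",
    "CumulatedDecayProfile",
    "radial_profile_from_image",
    "calibrate",
    "time_integrate",
    "scale_amount",
    "blend_profiles",
]


@dataclass(frozen=True)
class SpatioTemporalProfile:
    """Concentration (arbitrary units) vs time and radius for one drug.

    ``radii_um`` spans the spheroid interior and the medium region beyond
    ``schedule`` is the (start, end) of the drug's incubation in hours.
    """

    times_h: np.ndarray
    radii_um: np.ndarray
    values: np.ndarray  # (n_times, n_radii)
    drug_id: str
    schedule: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, float)
        r = np.asarray(self.radii_um, float)
        v = np.asarray(self.values, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial grid must be strictly increasing")
        if v.shape != (t.size, r.size):
            raise ValueError("values must have shape (n_times, n_radii)")
        if np.any(v < 0):
            raise ValueError("concentrations must be non-negative")
        if self.schedule[1] <= self.schedule[0]:
            raise ValueError("schedule end must follow start")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "radii_um", r)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        tt, rr = np.meshgrid(self.times_h, self.radii_um, indexing="ij")
        return pd.DataFrame({"time_h": tt.ravel(), "radius_um": rr.ravel(),
                             "value": self.values.ravel()})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drug_id: str,
                   schedule: tuple[float, float]) -> "SpatioTemporalProfile":
        wide = df.pivot(index="time_h", columns="radius_um", values="value")
        return cls(times_h=wide.index.to_numpy(),
                   radii_um=wide.columns.to_numpy(),
                   values=wide.to_numpy(), drug_id=drug_id, schedule=schedule)

    @classmethod
    def read(cls, path, drug_id: str,
             schedule: tuple[float, float]) -> "SpatioTemporalProfile":
        return cls.from_frame(pd.read_csv(path, sep="\t"), drug_id, schedule)


@dataclass(frozen=True)
class CellActivityProfile:
    """Per-cell activity (Bq) vs time and radius after calibration."""

    times_h: np.ndarray
    radii_um: np.ndarray
    activity_bq: np.ndarray  # (n_times, n_radii)
    drug_id: str
    schedule: tuple[float, float]
    molar_activity_gbq_per_mol: float | None = None


@dataclass(frozen=True)
class CumulatedDecayProfile:
    """Time-integrated mean decays per cell per radial shell for one drug."""

    radii_um: np.ndarray  # shell centers
    shell_width: float
    decays_per_cell: np.ndarray
    region: np.ndarray  # "spheroid" / "medium" per shell
    drug_id: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.decays_per_cell) < 0):
            raise ValueError("decays must be non-negative")
        if len(self.radii_um) != len(self.decays_per_cell):
            raise ValueError("radii and decays length mismatch")

    def value_at(self, radii) -> np.ndarray:
        """Profile value for cells at the given radial distances.

        Each cell receives the value of the shell containing its center.
        """
        idx = np.floor(np.asarray(radii, float) / self.shell_width).astype(int)
        if np.any(idx < 0) or np.any(idx >= len(self.radii_um)):
            raise ValueError("radius outside the profile's shell coverage")
        return np.asarray(self.decays_per_cell)[idx]

    def core_mean(self, r_max: float = 100.0) -> float:
        """Mean decays per cell within ``r_max`` of the center, weighting each
        shell by its cell population (proportional to the shell volume)."""
        r_in = self.radii_um - self.shell_width / 2
        r_out = self.radii_um + self.shell_width / 2
        sel = self.radii_um <= r_max
        w = r_out[sel] ** 3 - np.clip(r_in[sel], 0, None) ** 3
        return float(np.sum(w * self.decays_per_cell[sel]) / np.sum(w))

    def region_total(self, populations: np.ndarray | None = None) -> dict:
        """Total decays per region given shell populations (cells per shell)."""
        if populations is None:
            raise ValueError("shell populations required for totals")
        out = {}
        for reg in ("spheroid", "medium"):
            m = self.region == reg
            out[reg] = float(np.sum(self.decays_per_cell[m] * populations[m]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii_um, "region": self.region,
                             "decays_per_cell": self.decays_per_cell})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, drug_id: str) -> "CumulatedDecayProfile":
        df = pd.read_csv(path, sep="\t")
        r = df["radius_um"].to_numpy()
        width = float(np.median(np.diff(r)))
        return cls(radii_um=r, shell_width=width,
                   decays_per_cell=df["decays_per_cell"].to_numpy(),
                   region=df["region"].to_numpy(), drug_id=drug_id)


def radial_profile_from_image(image: np.ndarray, center: tuple[float, float],
                              ring_width_um: float,
                              pixel_size_um: float) -> pd.DataFrame:
    """Average intensity of concentric rings around ``center`` (pixel coords).

    Ring k collects pixels whose center distance falls in
    [k*ring_width, (k+1)*ring_width).  Rings containing no pixel get NaN
    (missing), never zero.  Returns a frame with radius_um (ring centers),
    mean_intensity and n_pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if ring_width_um <= 0 or pixel_size_um <= 0:
        raise ValueError("ring width and pixel size must be positive")
    cy, cx = center
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError("center must lie inside the image")
    yy, xx = np.indices(img.shape)
    dist_um = pixel_size_um * np.hypot(yy - cy, xx - cx)
    ring = np.floor(dist_um / ring_width_um).astype(int)
    n_rings = int(ring.max()) + 1
    counts = np.bincount(ring.ravel(), minlength=n_rings)
    sums = np.bincount(ring.ravel(), weights=img.ravel(), minlength=n_rings)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(n_rings) + 0.5) * ring_width_um
    return pd.DataFrame({"radius_um": radii, "mean_intensity": means,
                         "n_pixels": counts})


def calibrate(profile: SpatioTemporalProfile, applied_kbq_per_ml: float,
              site_volume_um3: float, spheroid_radius: float,
              half_life_days: float = AC225_HALF_LIFE_DAYS,
              molar_activity_gbq_per_mol: float | None = None,
              decay_correct: bool = True) -> CellActivityProfile:
    """Rescale a concentration profile to per-cell activity in Bq.

    The mean concentration in the medium region (radii beyond the spheroid)
    during the incubation window is taken as the plateau corresponding to the
    applied activity concentration at the moment the drug is added; all
    values are rescaled by that ratio and multiplied by the per-site volume.
    With ``decay_correct`` the activity additionally decays physically from
    the start of the drug's incubation, since fluorescent surrogates do not
    decay but the radiolabel does.
    """
    if applied_kbq_per_ml < 0:
        raise ValueError("applied activity must be non-negative")
    med = profile.radii_um > spheroid_radius
    if not med.any():
        raise ValueError("no medium region in the radial grid")
    t0, t1 = profile.schedule
    during = (profile.times_h >= t0) & (profile.times_h <= t1)
    plateau = float(np.mean(profile.values[np.ix_(during, med)]))
    if plateau <= 0:
        raise ValueError("medium plateau is zero; cannot calibrate")
    scale_kbq_per_ml = applied_kbq_per_ml / plateau
    # kBq/mL -> Bq per lattice site: 1e3 Bq/kBq * vol[um^3] * 1e-12 mL/um^3
    act = profile.values * scale_kbq_per_ml * 1e3 * site_volume_um3 * 1e-12
    if decay_correct:
        lam = decay_constant_per_s(half_life_days)
        dt_s = np.clip(profile.times_h - t0, 0, None) * SECONDS_PER_HOUR
        act = act * np.exp(-lam * dt_s)[:, None]
    return CellActivityProfile(times_h=profile.times_h,
                               radii_um=profile.radii_um, activity_bq=act,
                               drug_id=profile.drug_id,
                               schedule=profile.schedule,
                               molar_activity_gbq_per_mol=molar_activity_gbq_per_mol)


def time_integrate(activity: CellActivityProfile,
                   half_life_days: float = AC225_HALF_LIFE_DAYS,
                   spheroid_radius: float = 200.0,
                   biological_half_life_days: float | None = None,
                   shell_width: float | None = None) -> CumulatedDecayProfile:
    """Cumulated decays per cell: trapezoid over incubation plus washout tail.

    The integral runs over the sampled incubation window.  Shells inside the
    spheroid retain their end-of-incubation activity after washout, which is
    integrated analytically to infinity with the physical decay constant
    (optionally combined with a biological clearance half-life); medium
    shells are replaced by fresh medium at washout and receive no tail.
    """
    t = np.asarray(activity.times_h, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    a = np.asarray(activity.activity_bq, float)
    if np.any(a < 0):
        raise ValueError("activity must be non-negative")
    decays = np.trapezoid(a, t * SECONDS_PER_HOUR, axis=0)
    lam = decay_constant_per_s(half_life_days)
    if biological_half_life_days is not None:
        lam = lam + decay_constant_per_s(biological_half_life_days)
    region = np.where(activity.radii_um <= spheroid_radius, "spheroid", "medium")
    tail = np.where(region == "spheroid", a[-1] / lam, 0.0)
    if shell_width is None:
        r = activity.radii_um
        shell_width = float(np.median(np.diff(r))) if r.size > 1 \
            else max(2.0 * float(r[0]), 1.0)
    return CumulatedDecayProfile(radii_um=activity.radii_um,
                                 shell_width=shell_width,
                                 decays_per_cell=decays + tail, region=region,
                                 drug_id=activity.drug_id)


def scale_amount(profile: CumulatedDecayProfile,
                 multiplier: float) -> CumulatedDecayProfile:
    """Multiply all decays by an amount multiplier (activity apportionment)."""
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    return replace(profile,
                   decays_per_cell=profile.decays_per_cell * multiplier)


def blend_profiles(base: CumulatedDecayProfile, pre: CumulatedDecayProfile,
                   antibody_fraction: float, liposome_fraction: float,
                   reference_antibody_fraction: float = 0.5) -> CumulatedDecayProfile:
    """Interpolate/extrapolate payload penetration for a cocktail split.

    The preirradiation enhancement of payload penetration is assumed
    proportional to the antibody activity present during preirradiation:
    the full-amount shape at antibody fraction f is

        shape(f) = base + (f / f_ref) * (pre - base)

    where ``base`` is the profile without preirradiation and ``pre`` the
    profile measured with preirradiation at the reference antibody fraction
    (0.5).  The result is then scaled by the liposome activity fraction.
    f = 0.3 interpolates (weighted average); f = 0.7 extrapolates.
    Negative extrapolated values are clipped to zero.
    """
    if not np.allclose(base.radii_um, pre.radii_um):
        raise ValueError("base and pre profiles must share the radial grid")
    w = antibody_fraction / reference_antibody_fraction
    shape = base.decays_per_cell + w * (pre.decays_per_cell - base.decays_per_cell)
    if np.any(shape < 0):
        log.warning("blend_profiles: clipping %d negative extrapolated values",
                    int(np.sum(shape < 0)))
        shape = np.clip(shape, 0.0, None)
    return replace(base, decays_per_cell=liposome_fraction * shape,
                   drug_id=base.drug_id)
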