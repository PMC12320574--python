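# Methods

This note records the model, its parameter defaults, the numerical choices
and the limits of what the synthetic data can show. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cluster geometry

Cells are identical unit-density water spheres (radius 6 um, concentric
nucleus of radius 3 um) on a simple-cubic lattice with 12-um spacing. One
site is anchored exactly at the origin so a center cell exists for
dose-depth profiles; a site belongs to the cluster, and to the spheroid,
iff its center lies within the respective radius (half-open membership —
the boundary-inclusion rule is a package choice, made explicit because
different rules shift the cell count by a surface term). With the default
200-um spheroid radius this yields 19,381 spheroid cells, consistent with
the ~19,000 cells of a 400-um-diameter BT474 spheroid. The lattice extends
to a 350-um cluster radius; the outer 150-um shell of sites is labeled
`medium` and carries activity exactly like cells, which is how absorbed
dose from radioactivity in the culture medium enters the calculation.

## Alpha dosimetry

Only alpha emissions are transported. Beta and photon components of the
chain deposit a negligible dose at cellular distances compared with the
alphas and are omitted (a deliberate scope decision, not an approximation
error bound we claim).

The bundled nuclear data (`data/ac225_alpha_lines.tsv`) carries the
principal alpha lines of Ac-225 (four lines, total yield 1.0) and of its
daughters Fr-221, At-217 and Bi-213/Po-213 at secular-equilibrium yields
(total ~4 alphas per parent decay; the 2.16% direct Bi-213 alpha and the
97.84% Po-213 alpha are both present). The range-energy table
(`data/alpha_range_water.tsv`) follows standard stopping-power
compilations for 0.2-10 MeV alphas in liquid water; both directions are
interpolated with shape-preserving PCHIP splines, the inverse built from a
dense resampling of the forward curve so that `energy(range(E))`
round-trips to < 1e-6 MeV.

S-coefficients use straight-track CSDA transport: for an isotropic point
source at distance `d` from a nucleus center, the energy deposited along a
direction is the residual-energy difference across the track's chord
through the nucleus, and the direction average reduces to a 1-D integral
over the cosine of the polar angle (trapezoid rule, 2001 nodes; halving or
doubling the node count changes self-S by far less than 0.5%). Compartment
sources (cell surface, cytoplasm, nucleus) are Gauss-Legendre averages of
the point-source dose over the source region; because the nucleus is
concentric, a surface source is exactly a point source at the cell radius.
Cross-dose sources are resolved at their compartment geometry for
d <= 3 lattice spacings and collapsed to cell-center point sources beyond,
where the finite source size is negligible.

Two consequences worth knowing:

* the cross-dose kernel is not monotone in distance everywhere — the Bragg
  peak of the stopping power produces a local rise just before each line's
  end-of-range cutoff (visible near d ~ 70 um for the 8.38-MeV Po-213
  alpha); the kernel maximum still sits at the nearest-neighbor distance;
* retaining the daughters multiplies the surface-source self-dose of the
  6/3-um cell by ~3.5 rather than the yield ratio 4, because the
  longer-ranged daughter alphas carry more energy out of the cell. This
  ratio is the package's quantitative anchor (`scripts/acceptance.py`).

Validation: an independent Monte Carlo oracle (random source points,
cone-importance direction sampling, explicit Euler stepping of the
stopping power) reproduces the nearest-neighbor kernel within 2%, and a
fully absorbing sphere collects the spectrum's total energy within 1%.

## Cross-dose assembly

Cumulated decays are shell-wise constant, so per-cell cross-dose is the
3-D convolution of the decay field with the kernel sampled on lattice
offsets. The package evaluates this exactly with FFTs on the dense cubic
grid (the 350-um cluster is a 59^3 grid convolved with a 17^3 kernel)
instead of the shell-pair approximation one might use off-lattice: the
convolution is both exact and faster. A direct pairwise mode is retained
and tested against the FFT path on small clusters.

## Penetration and time integration

Measured profiles are fluorescence surrogates in arbitrary units; the only
absolute anchor is the applied activity concentration, so calibration
rescales each profile so that its medium plateau during incubation equals
the applied kBq/mL, multiplies by the per-site volume (12^3 um^3 =
1.728e-9 mL) and applies physical decay from the drug's addition time
(fluorophores do not decay; the radiolabel does).

Cumulated decays per cell are the trapezoidal integral of per-cell
activity over the incubation window plus a washout tail: spheroid shells
retain their end-of-incubation activity, integrated analytically to
complete physical decay (half-life 9.92 d), because outgrowth was followed
for 17 d after washout; medium shells are replaced by fresh medium and get
no tail. A biological clearance half-life can be combined with the
physical one for sensitivity analysis; the default assumes none. These
integration details are this package's definition of the pipeline stage —
the original instrument's internals are not published.

Cocktail splits reuse the full-amount profiles: the antibody profile is
scaled by its activity fraction (amount multiplier), and the liposome
payload profile is blended between the shape without preirradiation
(`base`) and the shape measured with preirradiation at the reference 50%
antibody case (`pre`):

    shape(f_ab) = base + (f_ab / 0.5) * (pre - base),

then scaled by the liposome fraction — i.e. the penetration enhancement is
assumed proportional to the antibody activity present during
preirradiation. f_ab = 0.3 interpolates; f_ab = 0.7 extrapolates, and
negative extrapolated values are clipped to zero with a logged warning.
The measured preirradiation condition (6.5 kBq/mL) is treated as
representing the 50% case (6.875 kBq/mL), as the source experiments did.

## Synthetic data generator

The real penetration data exist only as figures, so the generator emulates
their structure with simple closed forms:

* antibody: inward exponential from the spheroid surface (e-folding length
  40 um), peaking at the periphery (within 25 um of the surface), uptake
  ramping linearly over a 24-h incubation;
* liposome payload: nearly flat radial shape (30% center deficit) over the
  final 6 h (hours 18-24), mirroring the carriers' relative circulation
  times;
* preirradiation: multiplies the payload concentration in the 0-100 um
  core by `1 + (A_pre / 6.5 kBq/mL) * 0.42`, with a smooth logistic taper
  just outside the core (midpoint 120 um, width 4 um) chosen so the
  enhancement is uniform over the core used for calibration;
* medium: constant plateau during the drug's incubation; the profile
  relaxes exponentially (2.5-um scale) from the rim value to the plateau
  on the medium side of the boundary. Keeping the plateau out of the
  outermost *spheroid* shells matters: those shells receive the 14-day
  retention tail, and leaking medium-level concentration into them
  inflates peripheral dose and suppresses the medium's share of it;
* noise: multiplicative lognormal per (time, radius) sample, default
  CV 10%, seedable; CV 0 gives bit-reproducible profiles.

The two amplitude constants are calibrated (once, analytically exploiting
linearity) so that the noiseless pipeline at 6.875 kBq/mL reproduces the
measured core (0-100 um) decay means: 0.037 (antibody), 0.050 (payload),
0.071 (payload after 6.5 kBq/mL preirradiation) decays per cell — the
third following from the first two via the configured 42% enhancement.

What the generator does *not* emulate: binding-site-barrier kinetics,
payload release chemistry, spatial noise correlations, replicate-level
biological variability of penetration, or the true (unpublished) radial
shapes. Tests passing on synthetic profiles therefore validate the
machinery and the calibrated aggregate structure, not the fidelity of any
particular measured profile; predicted SFs differ quantitatively from the
published ones, and only printed scalar anchors and qualitative orderings
are asserted.

## Survival

`p(cell) = exp(-alpha*D - beta*D^2)` per cell, with alpha = 2.7 /Gy (the
alpha-particle LQ coefficient for this cell line) and beta = 0 by default:
high-LET survival is log-linear, and only alpha was specified for the
study; both parameters are exposed. The headline SF is the expectation
(mean p over cells within the 200-um spheroid radius — medium sites never
count); a Monte Carlo realization (independent Bernoulli per cell) is
reported alongside, since roughly-two-expected-survivors regimes are
exactly where the distinction matters.

Each drug is split into a spheroid part and a medium part with separate
daughter flags. Default assumptions mirror the study's conclusions: the
DOTA-chelated antibody loses its daughters inside the spheroid
(parent-only spectrum), liposomes retain them, and the medium is always in
equilibrium. Dose maps stay decomposed by (drug x source region) for
depth-profile reporting.

## Optimization

Decays, hence doses, are linear in molar activity at fixed carrier
concentration, and SF is monotone non-increasing in each activity, so the
feasible set is up-closed. The optimizer scans apportionment rays from the
lower-bound corner of the activity box, bisects each ray to the SF
constraint (activity tolerance 0.1%, constraint slack 1e-3 relative), and
refines the best apportionment by bounded golden-section search; a dense
grid search is the test oracle (agreement within 1% in objective). If even
the upper-bound corner misses the target, the problem is reported
infeasible with the best achievable SF. The optimization algorithm is this
package's own design; only the problem statement (objective, SF ceiling,
bounds) is taken from the study.

Carrier molar concentrations convert between activity concentration and
molar activity. The antibody default (5.556e-11 mol/mL) is fixed so that
the 6.5 kBq/mL preirradiation condition corresponds to the 1.17e5 GBq/mol
molar activity that anchors the cocktail's antibody lower bound. The
liposome's effective carrier (vesicle) concentration is not derivable from
a lipid molarity without knowing the aggregation number and payload
loading; the default 5e-10 mol/mL places the sterilizing activity range
within the 1e6 GBq/mol bound and is explicitly configurable.

## Numerical and degenerate-input choices

* Empty image rings are reported missing (NaN), never zero.
* Zero medium plateau, non-monotone grids, mismatched blend grids, unknown
  compartments/chains and out-of-domain energies raise errors.
* A constant regression response returns slope 0, r^2 = 0 by convention;
  zero-variance t-test replicates are an error.
* Single-shell decay profiles fall back to a shell width covering the
  shell's own extent.
* Problem sizes: the full cluster is 103,959 sites (59^3 grid); kernels
  tabulate ~300 distinct lattice distances; the default quadrature is 2001
  direction nodes (4001 in the acceptance script) and 16-32 radial nodes.

## Known limitations

* CSDA straight tracks: no energy-loss straggling, delta rays or
  microdosimetric fluctuations, so agreement with condensed-history codes
  is expected only at the few-percent level, and the daughter self-dose
  factor inherits the bundled stopping-power data (the 3.51 anchor is
  matched within a few tenths of a percent, but a different range table
  could shift it by several percent).
* Daughter transport is binary (retained in equilibrium or absent);
  recoil-range displacement and partial escape are not modeled.
* No bystander effects, repair kinetics, cell-cycle dependence, or
  proliferation during irradiation.
* The medium is static: no replenishment, convection, or daughter plating
  onto well walls (the latter was hypothesized in the source experiments
  to reduce medium dose).
* Optimization covers at most two simultaneous drugs and no normal-tissue
  toxicity constraints.
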