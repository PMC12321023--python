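# Methods

This note records the model, its assumptions, the numerical choices and
the limits of what the bundled synthetic fixtures can demonstrate.

## Scattering model

The measured quantity is the orientation-averaged excess intensity of
identical, uncorrelated particles in solution. For a set of point
scatterers with weights `w_i` (electrons) and normalized form factors
`f_i(q)` (`f_i(0) = 1`), the Debye equation gives

```
I(q) = sum_ij w_i w_j f_i(q) f_j(q) sinc(q r_ij),       sinc(0) = 1,
```

with `q = 4 pi sin(theta) / lambda` (not the crystallographic `s = q/2pi`
convention). Three scatterer categories enter with the amplitude
convention `A = A_a - A_x + c A_w`:

* **a** — structure atoms. When the input carries no explicit hydrogens,
  each heavy atom's covalent hydrogen count is read from the bundled
  residue table, added to its weight (`w = Z + n_H`) and reflected in a
  unified-group form factor. Groups are modeled as the heavy atom plus
  its hydrogens co-centered: the Gaussian-coefficient sum of the
  constituents renormalized at q = 0. Vacuum coefficients are the
  International Tables 4-Gaussian X-ray parameterization (via gemmi).
  The backbone amide nitrogen of every residue definition carries the
  in-chain (reduced-by-one) hydrogen count; no extra terminal hydrogen is
  added. Unknown residues or atom names fall back to zero hydrogens and
  plain vacuum factors.
* **x** — excluded-volume dummies (below), subtracted so that only the
  contrast against bulk solvent (rho0 = 0.334 e/A^3) remains.
* **w** — explicit dummy waters (10 e, water-group form factor) with a
  fitted amplitude scale `c`; the shell is *not* part of the excluded
  volume, so `c` models its density relative to bulk.

The intensity decomposes into six partials (aa, ax, aw, xx, xw, ww);
cross terms are stored with their sign and factor 2 included so that the
partials sum to the total identically (tested at 1e-10 relative).

## Distance binning

All pair distances are histogrammed once per (form-factor-class pair), so
the exact product `f_i f_j` applies to every pair — no effective-atom
approximation. Evaluating a q point is then linear in the number of
occupied bins. Self terms (i = j) are carried exactly at distance zero.
In weighted mode each bin is represented by the weight-averaged distance
of its contents, which removes the first-order binning error; unweighted
mode (bin centers) is retained for the error study. The default bin width
is 0.1 A, chosen so that the binned profile agrees with the exact
unbinned double sum to better than 1e-3 relative over q in [0.001, 1] on
the bundled fixtures — that agreement is itself an acceptance test.

`sinc` is evaluated through a cubic-spline lookup table (0.05 spacing,
extended on demand); its absolute error against direct evaluation is
below 1e-5, also tested. The internal q grid is 100 points linear on
[0.001, 1] 1/A; model values at experimental q come from cubic
interpolation, which is exact at the internal nodes.

### What the binning study does and does not show

On a highly ordered structure (cubic lattice, or the grid excluded-volume
dummies) the distance spectrum is discrete: weighted bins are essentially
exact while bin centers produce errors orders of magnitude larger at any
width. On a disordered cluster the comparison is run at fine widths
(0.01–0.04 A): there the bin-center offset of the sharply peaked bond
distances dominates and bin centers lose at every width, while the
weighted error grows monotonically with width. At coarse widths
(≳ 0.2 A) on desk-scale clusters the two error terms — the first-order
center bias and the second-order within-bin-variance (curvature) term —
become comparable and can fortuitously cancel for bin centers, so the
ordering is not guaranteed there; this regime is outside the default
operating point and is deliberately not part of the acceptance study.

## Occupancy grid

A world-axis-aligned cubic grid (default cell width 1 A) covers the
structure's bounding box plus padding sized so no hydration candidate
falls off-grid. Cell membership for spherical expansion uses the cell
center (unbiased volume estimate); the molecular volume is the marked
cell count times the cell volume, and converges to the analytic
union-of-spheres volume as the width shrinks (a 2 A sphere at 0.2 A cells
is recovered within 5%, ~0.8% in practice). Because the grid axes are
independent of the molecular orientation, profiles acquire a small
orientational dependence; fixtures pin the orientation and the effect is
absorbed by experimental uncertainties at realistic noise levels.

## Hydration shell

From every atom, 26 radial directions (the normalized nonzero offsets of
the 3x3x3 neighborhood, 45 degrees apart, closed under negation; 6- and
14-direction subsets are available) propose a water at

```
r = r_a + r_w + delta + N(0, sigma),    r_w = 1.4 A.
```

`delta = -0.5 A` pulls the shell slightly inside hard-sphere contact and
`sigma = 0.5 A` broadens the otherwise sharp first peak; both are
calibration constants of the empirical shell, exposed in the
configuration. Candidates are scored by re-casting the direction set from
the candidate with probe marks at {0.5, 1.0, 1.5} r_w and weights 3:2:1
(nearest mark inside the would-be water volume): the weighted fraction of
collision-free marks must reach 0.7. This crowding score corrects the
oversampling that negative surface curvature would otherwise cause inside
pockets (tested: cavity density does not exceed 1.5x the convex-surface
density on a hollow-shell fixture). Two hard constraints are enforced
exactly against continuous coordinates, not just grid cells: no water
center inside any vdW sphere, and water–water center separations of at
least `2 r_w` minus one cell diagonal. Accepted waters immediately mark
the grid so later candidates see them; processing order (atoms in input
order, directions lexicographic) and a single seeded jitter stream make
the shell fully deterministic. One normal variate is consumed per
candidate whether or not it is accepted, so acceptance decisions cannot
shift the stream.

The generated shell has its first surface-distance peak at
`r_w + delta ≈ 0.9 A` and an overall thickness of ~2–3 A — a single
shell; the secondary solvent-density peak near 7 A seen in simulation
studies is intentionally not modeled. The solvent density is empirical
and decoupled from physical water density, which is why `c` is fitted; a
structure-wide constant `c` cannot represent surfaces with varying
solvent affinity (e.g. lipids).

## Excluded-volume models

All models conserve electrons exactly: total dummy weight equals
`rho0 x` the model's own volume definition (tested at 1e-9 relative).

* **simple** (default): the average displaced electron count
  `rho0 V_grid / N` is placed at every atom with one common Gaussian form
  factor of radius 1.62 A. Equivalent to subtracting the average from the
  atomic weights; no fitted parameter, so the model cannot overfit.
* **fraser**: per-atom Gaussian dummies with radius
  `(V_species / pi^(3/2))^(1/3)` from a volume table. Four tables ship:
  Traube-derived atomic volumes, hard-sphere vdW volumes, and
  representative minimum-fluctuation / Voronoi-style group tables (the
  latter two are synthetic stand-ins with ~10% uncertainties — see their
  file headers). Implicit- and explicit-hydrogen variants are selected
  automatically; explicit-H heavy-atom volumes are smaller, making room
  for the hydrogens. The fitted scale acts through the common-mean-radius
  multiplier `gamma^3 exp(-q^2 r_m^2 (gamma^2 - 1)/4)` with `r_m` the
  structure's mean Gaussian radius, bounded to ±25% in volume
  (~±7.7% in radius) — the variation scale of tabulated group volumes.
  A 5% radius change corresponds to ~16% in volume, which is why volume,
  not radius, is the meaningful bound.
* **grid**: atoms re-expanded to `max(r_vdw, sqrt(3) w)` (one cell
  diagonal) close internal gaps and make the marking space filling; every
  marked cell gets a dummy at its center with weight `rho0 w^3` and a
  Gaussian of the cell volume. Adjacent dummies overlap strongly (their
  summed density midway between neighbors stays near the on-center
  density), approximating a homogeneous displaced density. Dummies with
  an unmarked 6-neighbor form the exterior layer; scaling only that layer
  by `gamma_s^3 in [max(1 - 1A/w, 0.05), 1 + 1A/w]` emulates a ±1 A
  surface-width change without re-binning. Hydration waters never enter
  the excluded volume (the exv mask is built from atoms only).

The grid-width study ratios the normalized partial `I_xx(q)/I_xx(0)`
against a 0.5 A reference: the deviation shrinks monotonically as the
cell width decreases from 2 to 1 A (at 60-atom toy scale; the same trend
motivates the 1 A default, with 2 A acceptable when only q ≤ 0.5 1/A
matters).

## Fitting

The model curve on the internal grid is interpolated to the data q and
fitted as `a I(q; c, gamma) + b`. For every trial of the nonlinear
parameters, (a, b) come from the closed-form 2x2 weighted normal
equations; the nonlinear search is scipy's differential evolution
(seeded, bounded, Sobol-initialized, default budget ~200 evaluations,
followed by a bounded local polish) over `c in [0, 2]` plus `gamma` when
the excluded-volume model exposes one (fraser always, grid when surface
fitting is on, simple never — 3 or 4 free parameters in total). Degrees
of freedom count every optimized parameter including a and b. Because all
histograms are precomputed and `c`/`gamma` act as analytic amplitude
multipliers, one objective evaluation is microseconds, making fits
near-instant and exactly reproducible for a fixed seed.

Self-fits on model-generated data recover noiseless parameters to better
than 1e-3 relative with chi2_r ~ 1e-8, and give chi2_r ≈ 1 under 2%
Gaussian noise; individual chi2_r values scatter with sd ≈ sqrt(2/nu)
(±0.14 at nu = 97), so occasional values near 1.4 are expected and an
extreme noise draw can exceed 1.5.

## Synthetic fixtures: scope and limits

`make_toy_structure` grows compact C/N/O clusters with sharply peaked
covalent bond lengths (1.23–1.78 A, sigma 0.01 A) and near-tetrahedral
angles under a 1.2 A clash floor — reproducing the peaked short-range
distance spectrum of real molecules, which the binning study depends on,
while remaining globular. Problem sizes throughout (20–150 atoms,
60-atom grid-width study, 100-point curves, 20 noise replicates) were
chosen so every diagnostic completes in seconds on one CPU. What passing
these tests does *not* show: behavior on real experimental curves with
inter-particle structure factors, oligomeric mixtures, flexible loops, or
instrument smearing — none of which the forward model represents — and
the synthetic volume tables stand in for, but do not reproduce, the
published group-volume measurements.

## Degenerate inputs and tie-breaks

Empty structures error early; solvent-only files strip to empty and
error downstream. A water placement returning zero waters is legal
(buried fixtures); `c` then has no effect and the fit reduces to the
remaining parameters. Rows with sigma ≤ 0 are dropped on read (logged);
duplicate q values collapse to the first occurrence. Unknown form-factor
species raise with the species and table named. The optimizer's global
stage may stop on its iteration budget; the polished best-so-far is
returned and flagged.
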