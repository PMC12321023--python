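# solscat

Solution X-ray scattering (SAXS) profiles of biomolecular structures,
computed from atomic coordinates and fitted to experimental curves.

Given a high-resolution structure (PDB), `solscat` evaluates the
orientation-averaged excess scattering intensity

```
I(q) = < | A_a(q) - A_x(q) + c A_w(q) |^2 >,
```

where `A_a` is the amplitude of the (implicit-hydrogen) atoms, `A_x` the
amplitude of the displaced-solvent (excluded-volume) dummies and `A_w` that
of an explicitly generated dummy-water hydration shell with fitted scale
`c`. Each amplitude is a Debye sum `sum_i w_i f_i(q) sinc(q r_i)` over
weighted point scatterers; the pair double sum is evaluated through
per-form-factor-class-pair distance histograms with *weighted* bins (each
bin represented by the weight-averaged distance of its contents), which
keeps the binned profile within a fraction of a percent of the exact
unbinned sum. The total intensity decomposes into six partial profiles
(`I_aa, I_ax, I_aw, I_xx, I_xw, I_ww`) that are always written alongside
the total.

Three excluded-volume models are available:

* **simple** (default) — the grid-estimated molecular volume, distributed
  evenly over the atoms with one common Gaussian form factor; no free
  excluded-volume parameter.
* **fraser** — per-species Gaussian dummy atoms (form factor
  `exp(-q^2 r_x^2 / 4)`, volume `V_x = pi^(3/2) r_x^3`) sized by a
  switchable volume table, with a fitted volume scale `gamma` bounded to
  ±25% in volume.
* **grid** — a space-filling lattice of cell-sized Gaussian dummies on a
  1 Å occupancy grid, split into interior and exterior layers; an optional
  scale on the exterior layer alone emulates growing or shrinking the
  surface by up to 1 Å.

Fits minimize the reduced chi-square `chi2_r = (1/nu) sum ((I - a I_m - b)/sigma)^2`
with the linear scale `a` and background `b` solved in closed form and the
nonlinear parameters (`c`, and `gamma`/`d` where applicable) found by a
seeded bounded global search.

Intended users: structural biologists and method developers who want
model-vs-data validation of atomic structures against solution scattering,
with full access to the partial profiles.

## Worked example

Everything runs offline; toy structures and synthetic datasets are
generated by the package itself.

```python
import numpy as np
from solscat import SaxsModel
from solscat.synthetic import make_toy_structure, make_synthetic_dataset

structure = make_toy_structure(30, seed=1)          # compact C/N/O cluster
dataset = make_synthetic_dataset(structure,         # model curve + 2% noise
                                 {"a": 1.2, "b": 0.5, "c": 0.9},
                                 noise_rel=0.02, seed=3)

model = SaxsModel(structure, dataset)               # simple exv model
results = model.fit(seed=1)
print(results.summary())
```

prints

```
SAXS profile fit
==============================================
excluded-volume model                   simple
data points                                100
q range [1/A]                        0.001 - 1
free parameters                              3
degrees of freedom (nu)                     97
----------------------------------------------
a  (linear scale)                      1.19173
b  (background)                       -8.63322
c  (hydration scale)                  0.903907
----------------------------------------------
reduced chi-square                     1.16537
```

The generating scale and hydration parameters (a = 1.2, c = 0.9) are
recovered within the noise, and `chi2_r ≈ 1` indicates a statistically
good fit. The constant background is the weakly determined parameter
here: intensities of order 10^5 with 2% uncertainties leave `b` a ~10^1
uncertainty band, so its estimate scatters around the true 0.5 without
affecting the others. `results.plot("fit.png")`
writes the fit-and-residuals figure, and
`model.profile().partials` exposes the six partial intensity curves.

The same pipeline is available from the shell:

```
solscat profile structure.pdb -o profile.dat      # q, total + 6 partials
solscat hydrate structure.pdb -o hydrated.pdb     # dummy-water shell as HOH
solscat fit structure.pdb data.dat --exv-mode grid
solscat diagnose --what binning                   # figure-style diagnostics
```

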