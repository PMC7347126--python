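# memclust

Quantification and stochastic modelling of ligand-induced receptor
clustering at the plasma membrane.

A sub-population of KDEL receptors resides at the cell surface, where
ligand binding triggers the formation of bright receptor clusters that are
visible in time-lapse confocal microscopy.  Some cell types (e.g.
macrophage lines) never develop such clusters, and the question of *why*
comes down to the balance between stochastic receptor loss (endocytosis)
and delivery (exocytosis), and to how efficiently delivered receptors dock
at preferred membrane sites.  `memclust` provides, in one tested package,
both sides of that analysis:

**Image quantification** (`memclust.imaging`, `memclust.labeling`)
— grayscale conversion, anisotropic-Gaussian local-background estimation,
ratio thresholding, Hoshen–Kopelman connected-component labeling (with
periodic boundaries for lattice states), logarithmically binned
cluster-size distributions `P(A)` with a least-squares decay exponent
`α` (`P(A) ~ A^-α`), cell geometry (equal-area circle diameter, Crofton
perimeter), per-perimeter signal-density time series, and segmentation of
the density time course into transient, exponential-growth and
steady-state regimes.

**Models** (`memclust.lattice`, `memclust.theory`, `memclust.growth`)
— a kinetic Monte Carlo simulator of endo/exocytosis on a periodic
membrane lattice (5 nm sites, 50–100 nm vesicles, Gaussian hot spots at
microtubule contact sites); the two-state master equation

    df/dt = −κ_endo f + κ_exo (1 − f),
    f(t) = f_s + (f0 − f_s) e^(−t/t_s),
    f_s = κ_exo/(κ_endo + κ_exo),   t_s = 1/(κ_endo + κ_exo)

with its rate-phase-space borders, detectability threshold line
`κ_endo = (1/f_c − 1) κ_exo` and effective rate `κ′_endo = n κ_endo`; and
a preferential-attachment growth model in which an arriving receptor
joins an existing cluster of size `A_i` with probability `β A_i / Σ A_j`,
giving the exponent relation **α = 1 + 1/β**.

**Synthetic microscopy** (`memclust.synthetic`) — a ground-truth scene
generator and renderer (power-law cluster sizes at hot spots inside an
elliptical cell, master-equation density time course, PSF blur and noise)
that makes the entire imaging pipeline testable end to end without
experimental data.

## Worked example

Predict and measure the cluster-size exponent at perfect docking
efficiency (β = 1):

```sh
$ memclust growth --beta 1 --n 100000 --seed 1 --out out/
predicted alpha 2.000, fitted alpha 2.000 +/- 0.085
```

The first number is the closed form `α = 1 + 1/β = 2`; the second is the
exponent fitted (weighted least squares on a log-binned histogram,
5 bins/decade) to the sizes produced by a 100 000-arrival growth
simulation.  Cluster sizes, the binned distribution and the fit are
written to `out/`.

Interrogate the rate phase space from Python:

```python
>>> from memclust import theory
>>> ref = theory.REFERENCE_RATES            # κ_endo = 1e-4/s, κ_exo = 0.5e-4/s
>>> theory.steady_state_fraction(ref)
0.3333333333333333
>>> theory.characteristic_time(ref)         # seconds
6666.666666666666
>>> theory.required_endo_rate(0.5e-4, 0.02) # rate pushing f_s down to 2%
0.00245
>>> theory.required_exo_rate(1e-4, 0.02)
2.0408163265306125e-06
>>> theory.characteristic_time(theory.RatePair(24.5e-4, 0.5e-4))
400.0
```

Reading: a cell with the reference rates keeps one third of its receptors
on the surface and saturates in ~110 min.  To make clustering
undetectable (steady surface fraction below 2%) endocytosis must be ~25×
faster (24.5×10⁻⁴/s) or exocytosis ~25× slower (0.02×10⁻⁴/s); at the
extreme-endocytosis point the system settles in 400 s ≈ 7 min.

Simulate the lattice model and analyze a rendered synthetic stack:

```sh
memclust simulate --config sim.cfg --seed 3 --out sim/     # trajectory CSV + saturation JSON
memclust synth --seed 4 --out syn/                          # multi-frame TIFF + ground truth
memclust analyze --input syn/stack.tiff --pixel-size 0.1 \
    --frame-interval 90 --sigma 12,12 --out analysis/
```

`analysis/analysis.json` then holds the cell geometry, the fitted size
exponent and the regime segmentation; cluster tables, the binned size
distribution and the density time series are written as CSV.

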