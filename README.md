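# slbnr

Slab-model neutron reflectometry of supported lipid bilayers (SLBs) at the
silicon–water interface: composition-based scattering-length densities (SLDs)
for mixed bacterial lipid extracts, an exact Abeles transfer-matrix
reflectivity engine, constraint-bound bilayer models, and simultaneous
co-refinement of several H₂O/D₂O solvent contrasts — plus a synthetic
time-of-flight data generator so the whole analysis chain can be validated by
parameter recovery without access to beamtime data.

It is written for membrane biophysicists characterizing reconstituted
bacterial membranes (e.g. *E. coli* total lipid extracts of ~75% PE, 13% PG,
12% cardiolipin, hydrogenated or per-deuterated) by specular neutron
reflection.

## The model

A measurement is described by a stack of homogeneous slabs between a
semi-infinite Si fronting and the aqueous backing: Si | SiO₂ | thin water gap
| bilayer layers | solvent. Each slab has a thickness d, an intrinsic SLD ρ, a
solvent fraction φ (ρ_eff = φ·ρ_w + (1−φ)·ρ), and a Gaussian roughness σ on
its substrate-side interface. Exact reflectivity is computed with the Abeles
optical matrix method — k_n = sqrt((Q/2)² − 4π(ρ_n − ρ_Si)), interface Fresnel
coefficients damped by the Névot–Croce factor exp(−2k_nk_{n+1}σ²) — and
smeared with a Gaussian dQ/Q resolution kernel.

Two bilayer parameterizations are provided:

* **Three-layer** (head | tail | head, hydrogenated extracts), with the head
  hydration *derived* from an equal area-per-molecule constraint,
  A = 2V_tails/(d_t(1−φ_t)), φ_h = 1 − V_head/(d_h·A), so the model stays a
  physically consistent bilayer.
* **One-layer + sparse vesicle layer** (per-deuterated extracts): a single
  slab plus, optionally per contrast, a water gap and a dilute second bilayer
  (solvent fraction 1 − c) tied to the SLB's thickness and SLD, modelling a
  few percent of unruptured surface-bound vesicles.

Headgroups exchange labile protons with the solvent, so the head SLD
interpolates between its H₂O and D₂O endpoints with the solvent D₂O fraction;
structural parameters are shared across all contrasts and fitted against all
datasets at once (bounded least squares, multistart, seeded).

## Worked example

Simulate a four-contrast series (H₂O, 40% D₂O, 60% D₂O, D₂O) from the bundled
hydrogenated-extract ground truth and co-refine the area-coupled three-layer
model from eight ±20%-jittered starts:

```python
from slbnr import co_refine, ground_truth_presets, simulate_contrast_series
from slbnr.simulate import InstrumentSpec

gt = ground_truth_presets()["hEcoli_50C"]
instrument = InstrumentSpec(q_min=0.005, q_max=0.3)   # ToF-like, 3% noise
data = simulate_contrast_series(gt.model, gt.contrasts, instrument, seed=1)
fit = co_refine(gt.model, data, n_starts=8, seed=1)
print(f"head {fit.params['d_head']:.2f} Å, tail {fit.params['d_tail']:.2f} Å, "
      f"total {fit.derived['total_thickness']:.2f} Å, "
      f"reduced chi2 {fit.reduced_chisq:.2f}")
```

prints

```
head 7.13 Å, tail 27.04 Å, total 41.29 Å, reduced chi2 0.81
```

i.e. the co-refinement recovers the 7 Å headgroup and 27 Å tail regions (41 Å
total bilayer) of the generating structure from noisy multi-contrast data; the
reduced χ² near 1 says the model describes the data to within the quoted
uncertainties. The area coupling keeps `fit.derived['area_per_molecule']`
(≈79 Å²) identical for heads and tails by construction.

The same workflow is available from the shell:

```sh
slbnr simulate -c config.yaml -o data/     # writes per-contrast .dat + truth.json
slbnr fit -c config.yaml data/sim_*.dat -o fit.json
slbnr report fit.json                      # layer table: d, solvent %, SLD, roughness
```

The `analysis/` directory re-enacts the full study as numbered scripts:
simulate all three ground-truth structures (01), co-refine the hydrogenated
(02) and per-deuterated (03) structures, test whether the sparse vesicle layer
is a necessary model extension (04: reduced χ² 0.75 with vs 1.26 without on
vesicle-containing data, and no spurious preference on vesicle-free control
data), and measure recovery error over 20 noise replicates per structure (05:
median absolute errors well inside the published uncertainties). Outputs land
under `results/`.

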