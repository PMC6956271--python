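# ocunano

Analysis pipeline for ocular drug delivery studies in which mucoadhesive
polymeric nanoparticles (NP) are dispersed in a thermosensitive ophthalmic
hydrogel (TSOH) — a vehicle that is instilled as a drop and gels on the eye.
The package covers the full chain of in-vitro and in-vivo computations such
a study needs:

- **formulation**: encapsulation efficiency `EE = (M_t − M_s)/M_t` and
  entrapped/free dose partitioning;
- **dialysis**: reversible drug–polymer/NP binding from dynamic-dialysis
  donor decay, `ln(100·C_d/C_d0) = ln 100 − K_m F_f t`. The free-drug
  control slope calibrates the membrane constant `K_m`; a formulation's
  slope over `K_m` gives its free fraction `F_f`, and `100(1 − F_f)` is the
  bound "Interaction %";
- **interrupted**: three-phase mass balance (NP matrix / dispersion medium /
  receiving phase) with the matrix fraction obtained by closure, and a
  retention check for "virtually constant" entrapment;
- **release**: Higuchi square-root-of-time fits `Q = k√t + b` of cumulative
  release from NP-loaded gels, with replicate slope comparison by Student's
  t-test;
- **microrheology**: DLS passive microrheology — Siegert relation,
  Gaussian-displacement inversion `MSD = −(6/q²) ln g₁`, and Mason's local
  power-law generalized Stokes–Einstein relation giving `G′`, `G″` and `η*`,
  used to score NP mucoadhesion by the viscosity thickening of a mucin
  dispersion;
- **sizing**: particle diameters from confocal micrographs as the FWHM
  (`2.3548 σ`) of Gaussian fits to equatorial intensity profiles, with
  two-population (aggregation) detection;
- **pk**: sparse-sampling noncompartmental analysis — linear trapezoidal
  `AUC₀₋₁₀`, Bailer-type variance propagation, relative AUC versus control,
  and a z/t exposure-comparison test for destructive (one sample per
  animal) designs;
- **simulate**: synthetic-data generators with known ground truth for every
  stage, so the whole pipeline is testable end to end without instrument
  data.

## Worked example

Infer drug–nanoparticle binding from a simulated dialysis experiment
(membrane constant 0.44 h⁻¹, true free fraction 0.523, 2% assay noise):

```python
from ocunano import analyze_runs
from ocunano.simulate import gen_dialysis_run

runs = [gen_dialysis_run(0.44, 1.0, noise=0.02, seed=r, label="Control",
                         replicate=r) for r in range(3)]
runs += [gen_dialysis_run(0.44, 0.523, noise=0.02, seed=100 + r,
                          label="QA-Ch", role="formulation", replicate=r)
         for r in range(3)]
print(analyze_runs(runs)[["label", "slope_mag", "km", "ff",
                          "interaction_pct"]].round(3))
```

```
     label  slope_mag    km     ff  interaction_pct
0  Control      0.440  0.44    NaN              NaN
1    QA-Ch      0.226  0.44  0.513           48.701
```

The control replicates recover the membrane constant (0.440 h⁻¹); the
formulation's slope ratio recovers the free fraction (0.513 vs the true
0.523), i.e. about 49% of the drug is reversibly bound to the dissolved
polymer.

The same round trip is available from the shell:

```sh
ocunano simulate --kind dialysis --seed 7 --out dialysis.csv
ocunano binding --input dialysis.csv --out binding.json
ocunano all --seed 4 --out run/      # every stage, simulate → analyze
```

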