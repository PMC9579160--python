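# smlight

Single-molecule fluorescence and solution-scattering analysis of
blue-light-induced conformational change, dimerization and partner binding
in the animal-like cryptochrome of *Chlamydomonas reinhardtii* (CraCRY) —
rebuilt as a tested, reusable Python pipeline with a synthetic-data module
so every stage runs without any experimental download.

## Who this is for

Single-molecule biophysicists who quantify:

* **conformational states by smFRET** — per-frame ratiometric efficiencies
  `E = I_A / (I_A + γ·I_D)` converted to dye-pair distances through the
  Förster relation `r = R₀ (1/E − 1)^{1/6}` (here `R₀ = 63.0 Å` for the
  ATTO550/ATTO647 pair), pooled into distance histograms and summarized by
  Gaussian state fits with molecule-bootstrap confidence intervals;
* **subunit stoichiometry by photobleaching step counting** — intensity
  change points from Gaussian GLR binary segmentation, one downward step =
  monomer, two = dimer;
* **complex formation by two-colour single-molecule pull-down** — spot
  detection (difference of Gaussians + subpixel centroids), dual-view
  channel registration, mutual nearest-neighbour colocalization, and the
  combined 2×2 (monomer/dimer × partner absent/present) tables that reveal
  mutual exclusivity between dimerization and partner binding;
* **in-vivo interaction by fluorescence lifetime** — maximum-likelihood
  mono-exponential fits to TCSPC delay histograms (mCitrine, τ ≈ 3.09 ns);
* **solution structure by SAXS** — Debye profiles from coordinates,
  Guinier analysis, dimensionless Kratky plots (globular peak at
  `(√3, 3/e)`), regularized p(r) inversion, and error-weighted model-to-data
  fits with residual series.

The condition presets in `smlight.synthetic` encode the system's measured
parameters: dark-state monomer 50 ± 13 Å (PHR↔CTE dye sites), lit-state
monomer 65 ± 12 Å, dimer 48 ± 12 Å, two-step bleaching 7.5 % (dark) →
25.1 % (lit), bait–prey colocalization ≈ 23 %, and the lit-condition joint
occupancy solved from the printed conditionals (dimer-without-partner
15.5 %, partner given monomer/dimer 25.1 %/10.4 %).

## Worked example

Simulate a dark-condition smFRET experiment at study scale (16 molecules,
0.1 s frames) and run the full pipeline — SNR screen, change-point
truncation at the first bleach, efficiency → distance, Gaussian fit:

```sh
$ smlight simulate fret --preset dark-monomer --n 16 --seed 1 --out demo_dark
wrote 16 fret traces to demo_dark
$ smlight analyze-fret --in demo_dark --r0 63.0 --out demo_result
distance 51.8 +/- 9.5 A (CI95 45.0-57.0, 2083 points, 14 molecules)
```

The fitted mean (51.8 Å) recovers the preset's 50 Å dark-state distance
within its bootstrap CI95; two of the 16 molecules were screened out (one
had no live acceptor, one bleached immediately), leaving 2083 per-frame
distance points — the same order as the ~2500 points the paper-scale
condition produces.  A stoichiometry run:

```sh
$ smlight simulate bleach --preset lit-monomer --n 400 --seed 2 --out demo_bleach
$ smlight count-steps --in demo_bleach --out demo_steps.csv
400 traces, dimer fraction 0.256 -> demo_steps.csv
```

recovers the lit-condition two-step fraction (25.6 % measured vs the 25.1 %
the preset encodes).  The same operations are available as library calls
(`smlight.fret.analyze_condition`, `smlight.trace_analysis.count_bleach_steps`,
`smlight.interactions.analyze_pulldown_fields`, `smlight.saxs.*`).

## Layout

| module | contents |
|---|---|
| `smlight.synthetic` | trace/spot/TCSPC/structure generators, condition presets |
| `smlight.trace_analysis` | SNR screen, change-point detection, step counting, lifetime MLE |
| `smlight.fret` | efficiency ↔ distance, histograms, Gaussian state fits |
| `smlight.interactions` | spot detection, registration, colocalization, 2×2 tables |
| `smlight.saxs` | Debye profiles, Guinier/Kratky, p(r) inversion, profile fitting |
| `smlight.io` | TSV/TIFF/CSV/JSON/3-column-text readers and writers |
| `smlight.cli` | `smlight simulate / count-steps / analyze-fret / coloc / fit-lifetime / saxs` |

See `docs/methods.md` for the models, defaults and known limitations.
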