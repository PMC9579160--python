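# Methods

This note documents the models behind each stage of the pipeline, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions a user should know before
trusting a number.

## Synthetic data: what the generators emulate

**FRET traces.** Each molecule carries one inter-dye distance drawn from a
Gaussian state distribution `N(state_mean, state_sd)` (rejection-sampled to
stay positive; a warning is raised if the rejection rate exceeds 1 %).  The
default jitter mode is *static-per-molecule*: the distance is fixed for the
molecule's lifetime and all per-frame variation enters through intensity
noise.  This matches the analysis convention of fitting the pooled
frame-level distance histogram with a single Gaussian per state — the
printed state SDs (13 Å dark, 12 Å lit and dimer) are *measured histogram
widths*, and the generator encodes them directly as conformational spread.
A consequence: per-frame intensity noise must stay subdominant, otherwise
the same width would be counted twice.  The FRET photon budget is therefore
3000 counts/frame with additive Gaussian noise of SD 150 per channel
(~2 Å of distance broadening at E ≈ 0.8), while the single-colour
stoichiometry traces use 300 counts/frame with noise SD 100 — per-frame
SNR 3.0, the top of the 2.5–3.0 screening band, which is where step
detection is actually stressed.

Signal model per frame at transfer efficiency `E = 1/(1 + (r/R₀)⁶)`,
`R₀ = 63.0 Å`: donor `B(1−E)`, acceptor `γ·B·E` (γ = 1 by default, exposed
because relative efficiencies may or may not carry a detection correction).
After the acceptor bleaches all signal moves to the donor channel; after
the donor bleaches both channels fall to background.  Bleach times are
exponential (defaults 0.03 s⁻¹ per dye for FRET traces, frame interval
0.1 s, 400 frames), giving ≈ 150 valid frames per molecule so that 16
molecules produce ~2.4 k pooled points — the scale of the emulated
experiment.

**Bleaching (stoichiometry) traces.** One or two fluorophores, each
contributing 300 counts/frame until its exponential bleach time (default
0.02 s⁻¹ over 3000 frames).  These rates were set once so that the two
failure modes of step counting are rare under the study conditions:
unbleached-by-end fluorophores (`e⁻⁶ ≈ 0.25 %`) and two bleach events
inside one minimum-detectable segment (~1 %).  Same-frame ties are
resampled so the true step count is well defined.  Blinking is excluded by
default (the analysis treats upward steps as blinks but the generator does
not produce them); `two_step_probability` is the *observed* two-step
fraction, with coincidence background folded in rather than added on top,
so recovery targets are well defined.

**Condition presets.** `dark-monomer` (50 ± 13 Å, two-step 7.5 %),
`lit-monomer` (65 ± 12 Å, 25.1 %), `lit-dimer` (48 ± 12 Å), and two
pull-down presets whose 2×2 joint occupancy (monomer/dimer × partner
absent/present) is solved exactly from three conditional probabilities.
For the lit condition these are P(partner|monomer) = 0.251,
P(dimer|no partner) = 0.155, P(partner|dimer) = 0.104, giving joint cells
(0.6494, 0.2176, 0.1191, 0.0138) and an overall interaction fraction of
23.1 %.  The dark-condition colocalization level is not separately
quantified in the emulated system; the preset assumes a background-scale
P(partner) = 0.05 with P(dimer|no partner) = 0.061 and a 1.5 %
partner-bound dimer rate.  This assumption is flagged here deliberately:
only the dark dimer-without-partner conditional is a measured quantity.

**Spot images.** Molecules placed uniformly (margin 8 px) on 256² px
fields at ~200 spots/field; each renders a Gaussian PSF of σ = 1.5 px with
amplitude 300·(subunit count) on a constant background of 100, Poisson shot
noise throughout; the prey channel is globally shifted by the dual-view
offset (default (2.0, −1.0) px).  Not emulated: EM-gain excess noise,
clock-induced charge, drift, non-uniform illumination, chromatic
magnification differences (the offset is a pure translation).

**TCSPC.** Photon delays are drawn from an exponential conditioned on the
detection window (inverse-CDF sampling) and histogrammed on a uniform grid
(defaults: 0.05 ns bins, 50 ns window).  No instrument response function,
afterpulsing or background photons — hence lifetime fits default to
`fit_start = 0`.

## Trace screening and change-point detection

**SNR screen.** SNR = (first-segment mean − final-segment mean) of a
provisional change-point pass, divided by the pooled within-segment SD;
accepted at SNR ≥ 2.5 by default.  Traces with no detectable bleach fall
back to mean/noise-SD and the report says so.  The exact formula behind the
published screening band is not documented anywhere we know of; signal
amplitude over pooled noise SD is one defensible reading and is stated here
so results are interpretable.

**Change-point model.** Recursive binary segmentation under a Gaussian
known-variance GLR: for a candidate single mean shift the statistic is
`(RSS₀ − RSS₁)/σ²`, χ²(1) under the null, with σ estimated robustly from
successive differences (median |Δ| / (√2·0.6745)) so undetected steps do
not inflate it.  The split is accepted when the maximal statistic clears
the χ²(1) critical value at level α = 0.01 Bonferroni-corrected for the
number of candidate positions in the segment; recursion keeps at least
`min_seg = 5` frames per side.  Two post-passes follow:

1. *Re-localization.* Each boundary is moved to the exact least-squares
   optimum between its neighbours (coordinate descent).  Greedy first
   splits compromise between two nearby true steps; without this pass the
   second boundary of close step pairs lands 3–4 frames early.
2. *Merging.* Adjacent segments merge when their means differ by less than
   `merge_k·σ` (merge_k = 1) **or** when the two-sample z statistic
   `|Δmean|/(σ√(1/n₁+1/n₂))` is below `merge_z = 3.5`.  The second
   condition removes short noisy segments whose offset is large in counts
   but statistically insignificant — without it ~1 % of two-step traces
   grow a spurious third step and are wrongly rejected.

On noiseless piecewise-constant inputs with at most two steps the result
equals exhaustive least-squares segmentation (verified against a brute-force
oracle).  Lowering α never adds boundaries (the split location does not
depend on α, only its acceptance).  Under the study conditions, 96 % of
two-step traces at SNR 3 yield both bleach frames within ±2 frames; the
remainder are structural — bleach collisions within a few frames, bleaches
inside the first `min_seg` frames, or a fluorophore outliving the movie.

**Step counting.** Only downward boundaries count; a down-step within 3
frames of a preceding up-step is treated as the same fluorophore
re-bleaching after a blink; down-steps smaller than 25 % of the largest one
are dropped as drift.  One step ⇒ monomer, two ⇒ dimer, zero or more than
two ⇒ rejected (rejected spots are excluded from interaction tables, never
imputed; their count is reported).  Traces with more than two steps are
reported as rejected rather than guessed to be oligomers.

**Lifetime fit.** Multinomial maximum likelihood over window-truncated
exponential bin probabilities, 1-D bounded minimization; SE from the
numerical observed information.  Noiseless self-consistency is exact, and
doubling all counts halves the SE by √2 as the likelihood scaling demands.

## The FRET distance pipeline

Per molecule: screen → change-point detection in both channels → truncation
at the first downward boundary of either channel (FRET is meaningless after
either dye dies) → per-frame `E = (A−bg_A)/((A−bg_A) + γ(D−bg_D))` →
`r = R₀(1/E−1)^{1/6}`.  Two additional guards implement the "effective
molecule" notion: a minimum valid window of 5 frames, and a live-acceptor
check (mean acceptor signal ≥ 2× its robust noise within the window), which
excludes donor-only molecules whose acceptor was dark from frame 0 and
would otherwise contribute pure-noise distances.

Efficiencies are clipped to `[10⁻³, 1−10⁻³]` before inversion and frames at
the clip boundary are excluded from histograms as saturated.  **Saturation
band:** at the default photon budget, donor counts fall below the noise for
distances under ~R₀/2, so per-frame efficiencies there scatter across 1 and
the left tail of a distance distribution is partially censored.  For the
dark state (50 ± 13 Å) this shifts the fitted mean up by roughly +1.7 Å
relative to the nominal state mean — a property of ratiometric E→r
inversion at finite SNR, shared by the real measurement, not an artifact of
this implementation.  Parameter-recovery tests therefore measure the
estimator against the realized (window-weighted) truth of the analyzed
molecules; condition-level acceptance checks use bootstrap CIs that are
wide enough (±5 Å at 16 molecules) to absorb the censoring.

Histograms pool frames across molecules unweighted (default bin 2 Å,
density normalized to integrate to 1); molecules therefore enter with
weight proportional to their bleach-limited window length.  The Gaussian
state fit is the closed-form MLE (sample mean, population SD); the 95% CI
of the mean is a nonparametric bootstrap over *molecules* (default 1000
resamples, seeded), because frames within a molecule are strongly
correlated and a frame-level bootstrap would be wildly overconfident.  A
multimodality warning (Sarle's bimodality coefficient > 0.555 with excess
kurtosis < −0.6) suggests per-state fitting; the kurtosis gate keeps
skewed-but-unimodal pooled histograms — the normal case at small molecule
counts — from tripping it.  A two-component fit is deliberately not the
default; each condition is summarized by one Gaussian.

## Colocalization and interaction tables

Spot detection: difference of Gaussians at (σ, 1.6σ), 3×3 local maxima
above 5× the MAD-based noise of the filtered image, subpixel centroids on
the background-subtracted image in a ±2σ window.  At the default densities
recall is ~97 % with no false positives; the residual misses are molecule
pairs closer than ~4 px that merge into one diffraction-limited spot, and
brighter (dimer) spots are detected slightly more reliably than monomers —
both effects the real assay shares.

Registration: integer grid search (±8 px) maximizing pair counts within
3 px, then iterated mean-displacement refinement of mutual
nearest-neighbour pairs; recovers an injected offset to < 0.2 px at the
default SNR.  Pairing: mutual nearest neighbours within 2 px (≈ 1.3 PSF σ);
mutuality prevents double counting at moderate density.  The pairing radius
is a package default, documented rather than inherited: no published
criterion exists for the emulated assay.

Chance colocalization `1 − exp(−ρπr²)` (ρ = prey density) is computed and
reported — about 1 % at the default densities — but **not** subtracted from
the raw fractions, matching how such assays are conventionally reported
against measured backgrounds.  Conditional fractions are computed in both
directions from the same 2×2 counts (dimer fraction given partner status;
partner fraction given stoichiometry), so the two normalizations of the
rare dimer-with-partner cell are both available.  Group-wise summaries
(mean and SD across acquisition groups, assigned round-robin) mirror
date-grouped error bars; with a single group the SD is reported as
not-available, never as zero.

## Scattering tools

**Debye profiles.** `I(q) = Σᵢⱼ fᵢfⱼ sin(qd)/(qd)` with the q→0 and d→0
limits handled via the sinc form; exact O(N²) reference plus a
pair-distance-histogram acceleration (4000 bins) that agrees to ≲0.1 % and
engages automatically above 2000 points.  Coordinates from PDB files are
reduced to one dummy scatterer per residue at the Cα with the residue
electron count as weight; no solvent or excluded-volume terms — profiles
support shape-level analysis (Guinier, Kratky, p(r), relative fits), not
absolute comparison with measured protein curves.

**Guinier.** Iterated weighted regression of ln I on q² restricted to
q·Rg ≤ 1.3 (the globular convention).  The Guinier expansion is exact only
as q→0: for a solid sphere the fitted Rg at qRg ≤ 1.3 is biased +1.8 %,
falling to +0.7 % at qRg ≤ 0.8 — precision checks against the closed form
`Rg = R√(3/5)` therefore use the tighter range.  A non-negative low-q slope
raises an error rather than returning an imaginary Rg.

**Dimensionless Kratky.** `(qRg)²·I/I₀` vs `qRg`, peak refined by a local
parabola; an ideal globular particle peaks at `(√3, 3/e ≈ 1.104)`, a
Gaussian chain plateaus with the peak shifted right — both verified against
closed forms.

**p(r) inversion.** Non-negative piecewise-linear p(r) on a uniform grid
(default 101 points) with endpoints pinned to zero, fitted by NNLS to the
error-weighted curve with a second-difference smoothness penalty; α chosen
by the discrete-curvature corner of the L-curve when not supplied.  The
simpler basis (vs an oscillatory sine series) is oracle-checked: the sphere
p(r) is recovered to < 0.5 % normalized RMS and the second-moment Rg
matches Guinier within 2 %.  A "dmax likely underestimated" warning fires
when χ² exceeds 10× the best achievable with the extent constraint relaxed
(reference fit at 2× dmax, minimal smoothing) — the best fit *at* a wrong
dmax is itself poor, so the reference must relax the constraint to see the
problem.

**Profile fitting.** Linear interpolation of the model onto the overlapping
experimental q range, least-squares scale (optional constant offset, off by
default), reduced chi `χ = √(mean(((I_e − cI_m)/σ_e)²))` with N reported,
and the residual series `(I_e − cI_m)/σ_e` returned for plotting under the
fit.

## Problem sizes and determinism

Every generator is deterministic given (config, seed); dataset-level
generation threads a single RNG through molecules in a fixed order.
Recovery tests run at the study's own scales (16–65 molecules for smFRET
conditions; 2000 traces or spots for fraction recovery; 10⁵ photons for
lifetimes), with replicate averaging where a single small-n session is
dominated by molecule-sampling noise (a 16-molecule session has ~4.6 Å SD
on its fitted mean because bleach-limited windows concentrate weight in
~8 effective molecules).  The acceptance script averages 5 replicate
sessions for the 16- and 22-molecule conditions, 3 for the rest.

## Known limitations

* Gaussian additive camera noise; no EM-gain excess noise factor.
* Single-exponential photobleaching; no blinking in generated data (the
  blink policy in step counting is exercised on constructed traces only).
* No IRF or background model in lifetime fitting; tail fits only.
* Distances below ~R₀/2 are censored by efficiency saturation at the
  default photon budget (see above).
* Per-residue dummy form factors and no hydration layer in Debye profiles.
* Channel registration is translation-only.
* Hidden-Markov FRET state dynamics, accessible-volume dye modeling, and
  multi-exponential lifetime unmixing are out of scope.
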