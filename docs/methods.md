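# Methods

`andromass` reimplements, as a tested pipeline, the data-analysis side of a
qualitative/quantitative LC-TOF/MS workflow for *Andrographis paniculata*
constituents: exact-mass and adduct calculus, rule-based classification of
composite in-source spectra into diterpene-lactone and flavone classes,
narrow-window extracted-ion-chromatogram (nwXIC) quantitation, and the
standard method-validation statistics. Everything runs on in-table worked
examples and seeded synthetic runs; no instrument data are required.

## Exact-mass calculus

All arithmetic is over integer elemental compositions with monoisotopic
(lightest-isotope) masses from a plain-text registry (`data/elements.tsv`:
C 12, H 1.0078250319, N 14.0030740052, O 15.9949146221, Na, K). Adduct m/z
follows

    m/z = (multiplicity x M + mass(delta)) / charge

with the registry in `data/adducts.tsv`. The default convention is the
**hydrogen-atom** convention: the `[M+H]+` delta is one H atom and no
electron mass is subtracted. This is what TOF vendor software prints as
"calculated" values, and it reproduces every published calculated
protonated-molecule mass in this system to within 0.5 mDa; an
electron-corrected mode is available as a flag (`adduct_mz(...,
electron_correction=True)`, -0.00055 Da per charge).

Formula enumeration inverts the adduct relation to a neutral-mass window
and walks the bounded CHNO lattice, solving the admissible H range per
(C, N, O) cell directly from the window, so it is exhaustive by
construction (tested against a brute-force nested loop). Candidates are
filtered to ring-plus-double-bond equivalents RDBE = (2C + 2 + N - H)/2 in
[0, 25] and integer-valued (even-electron protonated molecules), then
ranked by |ppm error|, total atom count, Hill string. Na/K are permitted
only as adduct deltas, never in the neutral composition; isotope patterns
are not modelled (the workflow matches monoisotopic masses only).

## Fragmentation annotation

Spectra are composite in-source full scans (hot-cone acquisition):
precursor and fragments co-occur at one chromatographic apex, so no MS/MS
isolation is modelled. Annotation explains mass *differences* —
precursor-to-fragment and fragment-to-fragment; ions above the precursor
(sodiated, ammoniated, proton-bound dimers) are never loss products and are
excluded from the edge graph.

The composite loss vocabulary is 0–4 waters plus at most one of
{CH2, CO, CH3, 2xCH3, glucosyl C6H10O5 162.0528, glucuronyl C6H8O6
176.0321, CH2O}, matched at two tiers:

* **exact** — |observed - monoisotopic loss| <= 15 mDa;
* **nominal** — |observed - round(loss)| <= 0.3 Da, as a fallback.

The nominal tier exists because published ion tables are not always
internally consistent at exact-mass level (e.g. a printed "[M+H-CO]+" ion
27.887 Da below its precursor, or a fragment printed with a transposed
digit); the tier system absorbs such rows without editing the data, and
every edge records the tier it matched at. Nominal ties (2xCH3 vs CH2O,
both nominal 30) are broken by a fixed preference order that ranks CH2O
last, matching how practitioners read a nominal-30 loss from a
dimethoxylated flavone.

Classes are called by the first matching fingerprint in a configurable
precedence (`data/rules.yaml`):

1. **bis-diterpene** — precursor > 600 Da, a precursor-anchored edge
   carrying >= 3 waters (pure or composite, so a -3H2O-CH2 chain counts),
   and a dehydrated-monomer fragment within +-0.05 of 297.18 or 269.18;
2. **diterpene glucoside** — an exact-tier pure-glucosyl edge off the
   precursor with subsequent water loss from the aglycone ion (the
   exact-tier requirement stops nominal-162 coincidences in flavones);
3. **diterpene monomer** — any sugar-free edge carrying >= 2 waters
   (polyhydroxylated labdane skeletons dehydrate successively);
4. **flavone aglycone** — precursor < 400 Da with a methyl loss (exact
   tier) or CO loss (either tier), the classic flavone ring chemistry;
5. **flavone O-glycoside** — a fragment inside the aglycone windows
   {271.060, 287.055, 301.071, 315.087} +- 0.010 (loose fallback +-0.1),
   regardless of whether the precursor-aglycone difference matches a
   residue — deliberately, since one unknown precursor is inconsistent
   with any glycoside composition yet plainly shows a flavone aglycone.

The precedence (bis > glucoside > monomer > aglycone > glycoside) resolves
compounds that carry both sugar and water losses and keeps diterpenes with
incidental nominal-CO fragment pairs out of the flavone classes. Sugar
residues (hexosyl/glucuronyl) are assigned from the precursor-aglycone
difference under the exact tolerance. Classification is a pure function of
the spectrum and the rule set; peak order is irrelevant.

Positional isomers are out of scope — a single-stage accurate-mass method
cannot place a hydroxyl, and the pipeline does not pretend to.

## Chromatography

Scan series are centroided MS1 runs. Lock-mass correction finds, per scan,
the most intense centroid within +-50 mDa of the reference (protonated
leucine enkephalin, 556.2771) and rescales that scan's mass axis by
reference/observed; scans lacking the reference borrow the nearest scan's
factor (warning below 50% coverage, error at zero). The correction is
multiplicative, hence idempotent up to the reference ion's own mass noise.

nwXICs sum centroid intensities within a **full** window of 20 mDa
(+-10 mDa) per scan — the conventional reading of a quoted "20 mDa
window"; the width is a parameter.

Peak detection: baseline = 10th-percentile of the trace; noise = 1.4826 x
MAD of the trace after discarding its top decile (the candidate peak
region), which stays robust while peaks occupy a minority of scans;
peaks = contiguous regions above baseline + min_snr x noise, with
sub-threshold gaps of one scan bridged so a single centroid dropout cannot
split a peak; area = trapezoid of (trace - baseline) including the
crossing flanks. Zero estimated noise with nonzero signal reports S/N as
+infinity. For dilution series, `window_snr` scores S/N detection-free as
(window maximum - median)/noise; the median offset is essential, since a
low-quantile baseline would credit every blank with ~1 sigma of signal.

## Quantitation and validation statistics

Calibration is least squares of response on concentration (unweighted by
default; 1/x weighting available for two-decade ranges), R^2 = 1 -
SSres/SStot. Back-calculation inverts the line and flags results below the
LOQ or above the validated range. LOD and LOQ are the smallest
concentrations of a dilution series whose S/N reaches 3 and 10
respectively (optionally linearly interpolated between bracketing levels);
a non-monotone S/N profile is warned about and isotonically projected
first. Precision is the relative standard deviation (n-1 denominator);
matrix effects are relative recovery, (spiked - original)/added x 100%.

The quantifier-ion map targets 297.1798 for both andrographolide
([M+H-3H2O]+) and dehydroandrographolide ([M+H-2H2O]+) — the two ions are
isobaric to ~10 uDa (calc 297.1854/297.1855), which is precisely why one
narrow-window trace shows both compounds, resolved in time at 5.11 and
7.57 min — and 319.2288 for neoandrographolide ([M+H-Glc]+).

## Synthetic data

`table1_fixture()` ships the fifteen published composite ion tables
verbatim (printed m/z, uniform nominal intensities, published retention
times) — including their internal inconsistencies, which the tier system,
not the fixture, absorbs.

`generate_run` synthesizes centroided MS1 runs from compound templates
(composition, class, retention time, diagnostic ions with relative
intensities): Gaussian elution, per-ion Gaussian ppm mass noise,
multiplicative intensity noise, a chemical baseline riding on every
analyte ion channel, an optional systematic mass-axis bias applied before
noise (so lock-mass correction is testable against truth), and a
continuously present lock-mass ion. Ground truth (amplitudes, apex times,
closed-form areas h x sigma x sqrt(2 pi)) accompanies every run, and all
generators are byte-identical under a fixed seed.

Default conditions, chosen once to emulate the study this models:
3 ppm mass-noise sd (published observed-vs-calculated errors span roughly
1–9 ppm), 2% intensity CV (intra-day precision < 3.3%), peak sigma
0.05 min on a 10-min gradient, scan interval 0.01 min (the instrument's
0.1 s scans thinned 6x to keep desk-scale runs fast), baseline level
20 / sd 15 against a response of 1000 area units per ug/mL — which places
the measured S/N 3 and 10 crossings near 0.02–0.05 and 0.2 ug/mL, the
magnitudes reported for these analytes. Calibration tables truncate noisy
responses at zero (detectors report no negative areas) but keep exact
design values in the noiseless case, so a noiseless table reproduces its
generating equation — including a negative intercept — verbatim.

What the generator does *not* emulate: isotope envelopes, detector
saturation, chromatographic drift and tailing, correlated chemical noise,
real matrix interferences beyond a per-compound suppression factor, or
extraction-yield chemistry. Passing tests therefore demonstrate the
correctness and stability of the computational pipeline under the stated
noise model, not instrument-grade performance on real extracts; the
published sample-content table itself is not reproducible without the
original raw data, and no attempt is made to fake it.

## Numerical choices and edge cases

* Mass tolerances are symmetric windows, ppm anchored at the first
  argument; mDa tolerances are absolute.
* Formula-search ties: |ppm|, then atom count, then Hill string — any
  stable order would do; this one is documented and tested.
* Empty spectra annotate to an empty edge list and class `unknown` (never
  an error); unexplained differences simply yield no edge.
* `precision_rsd` returns exactly 0 for identical replicates, guarding
  float round-off in the mean.
* Degenerate calibrations (one point, one distinct level, zero slope) are
  errors; an unreached S/N threshold is the sentinel "not determined",
  not an error.
* Apex-spectrum extraction from full runs drops centroids below 1% of the
  scan base peak so co-monitored channels' chemical baseline is not
  mistaken for fragment ions, and ignores TIC excursions below 1% of the
  largest peak's area.

## Problem sizes

Test and analysis runs use 10-min runs at 0.01-min scan intervals (1000
scans), five-level pipeline calibrations, 100-seed Monte-Carlo loops for
end-to-end recovery and linearity, and 200 seeds per class for
classification robustness — sizes chosen so the whole suite exercises
every stage in well under a minute per module.
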