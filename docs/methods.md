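# Methods

This note documents the models behind `pyrotrace`, the defaults they
ship with, and what the synthetic experiments do and do not establish.

## Spectral model and preprocessing

A spectrum is a strictly increasing wavenumber axis (cm⁻¹) with
matching intensities. Default grids: Raman 200–1,800 cm⁻¹ at 2 cm⁻¹
(the model input is resampled to 4 cm⁻¹); FTIR 400–4,000 cm⁻¹ at
4 cm⁻¹, matching common transmission-FTIR acquisition settings (32
scans, 4 cm⁻¹ resolution). I/O covers single-block JCAMP-DX
(`(XY..XY)` pairs and `X++(Y..Y)` tables, 1/CM abscissa) and two-column
CSV (`wavenumber_cm1,intensity`); descending axes are reversed on read.

Preprocessing is a `PreprocessRecipe` bound to whatever model consumes
it: linear interpolation onto the target grid (extrapolation refused),
optional Savitzky–Golay smoothing (odd window ≥ 5), baseline removal,
normalization. The default baseline is asymmetric least squares
(Eilers-style; λ = 1e5, p = 0.01, 10 iterations) — smooth,
reproducible, and standard for Raman fluorescence backgrounds. λ is
data-dependent in practice: broad bands (FWHM ≳ 25 cm⁻¹) need a
stiffer λ (~1e7) or the baseline sags into the peak. A rolling-minimum
baseline is available as a cruder alternative. Baseline fitting is
deliberately excluded from the idempotence guarantee: iterated ALS
keeps chasing the lower noise envelope; regridding plus normalization
is a true projection. Normalization is per-spectrum max-1 by default
(area-1 and unit-vector are available); whether normalization should be
per spectrum or per spectral region is genuinely open, so the choice is
exposed in the recipe.

Noise is estimated as 1.4826 × MAD of linearly detrended intensities in
a signal-free window (≥ 20 points); for FTIR the default quiet window
is 1,900–2,400 cm⁻¹, free of apatite, quartz, clay and calcite bands.

## Synthetic-data generator

The generator is first-class code: it defines the study conditions for
every downstream test. It emulates four diagnostic heat responses with
pseudo-Voigt bands (Gaussian fraction 0.7 for flint Raman) and logistic
temperature responses parameterized by a midpoint T50 and width —
the field only establishes that these alterations are irreversible and
monotone-ish, not their functional form, so smooth logistics are the
simplest adequate choice.

**Flint UV Raman** (per temperature T in 20–1,200 °C): α-quartz band at
465 cm⁻¹ (amplitude 1, FWHM 8 cm⁻¹ + 1 cm⁻¹ per 100 °C); moganite at
501 cm⁻¹ with amplitude = moganite_fraction × logistic decay
(T50 = 425 °C, width 80 °C); carbon D/G bands at 1,350/1,600 cm⁻¹
(FWHM 180/90) with a rise-then-fall response (growth T50 = 350 °C,
width 60; decline centered at 600 + 150 °C, width 150); a smooth
Chebyshev baseline; additive Gaussian noise at SNR 50 (relative to the
quartz band). Inter-source variability enters through the moganite
fraction (0.3–0.9), carbon load (0.5–1.5), baseline coefficients, and
multiplicative jitter (0.8–1.25) on the response midpoints — this is
what makes held-out-source generalization a real test rather than
interpolation. On 20–900 °C the feature vector (moganite ratio, D, G,
quartz width) identifies temperature: the moganite ratio and quartz
width are strictly monotone and disambiguate the D/G branches.

**Bone/tusk FTIR**: phosphate ν4 doublet at 565/603 cm⁻¹ (FWHM 14,
tusk 10 — the tusk flag is cosmetic), ν3 at 1,035 cm⁻¹, carbonate at
872/1,415 cm⁻¹, collagen amide I at 1,660 cm⁻¹ decaying with heating
(logistic, T50 = 350 °C). The 630 cm⁻¹ hydroxyl band has amplitude
exactly 0 below the hydroxylation onset (600 °C) and appears at half
strength right at the onset, growing to full strength 300 °C later —
it marks a recrystallization transition, not a gradual accumulation.
Apatite bands use a Gaussian fraction of 0.85: KBr-pellet bands are
near-Gaussian, and heavier Lorentzian tails would fill the ν4/630
valley that real spectra show. Default SNR 100.

**Sediment FTIR**: quartz (1,084; 797/778 doublet; 694 cm⁻¹), clay
(Si–O at 1,032; Al–OH deformation at 915; structural-water OH at
3,620/3,695 cm⁻¹) and optional calcite (1,420; 874; 713 cm⁻¹),
weighted by composition. The hydroxyl-linked clay bands scale with a
smoothstep retention: 1 at or below the dehydroxylation onset
(450 °C), exactly 0 from onset + 100 °C.

**Site simulation**: an excavation grid of 5 × 5 m squares (default
2 × 3, labeled K3–L5); artifacts get planar coordinates, log-normal
size attributes (length median 35 mm, thickness 8 mm, σ_log = 0.4 —
small-flake assemblages), a type label, a true temperature from a
homogeneous, patchy (one ~2 m hot patch) or random field, and
replicate Raman spectra (27 by default). Fauna get one FTIR spectrum
each; an optional burnt quota places exactly that many fragments past
the onset, clustered into one square as burnt material concentrates in
real assemblages.

What the generator does *not* emulate: real flint mineralogy beyond the
four diagnostic features, diagenetic alteration of bone mineral,
atmospheric CO₂/H₂O artifacts, detector etaloning, cosmic rays, or
spectra of mixed materials. Passing tests therefore show that the
algorithms recover what the model encodes — not that the instrument
chain on real material behaves this well.

## Thermometer

Architectures: `cnn1d` — three convolution blocks (kernel 9, channels
16/32/64, ReLU, stride-2 average pooling), global average pooling, a
dense head (32) and a scalar output; `fcann` — dense layers (64, 32)
over the flattened spectrum. Both are implemented in seeded numpy with
hand-derived backpropagation (validated against central finite
differences in the test suite) and trained with Adam (lr 1e-3, batch
64, 200 epochs by default) on mean squared error over standardized
temperatures. Predictions are clipped to the training temperature
range — the calibration design gives the model no basis for
extrapolation. Checkpoints are a single `.npz` with a JSON architecture
header plus weights, and reload to identical predictions.

The desk-scale calibration experiment uses 9 temperatures (20, 200,
300, …, 900 °C) × 8 sources × 27 replicates with the last two sources
held out, at reduced settings (channels 8/16/32, 40 epochs, lr 2e-3) —
they converge comfortably on the synthetic bands and keep the full run
around a minute on one CPU. Per-artifact estimates are the arithmetic
mean over replicates (with sample SD); averaging over replicates is
what shrinks the artifact-level MAE below the per-spectrum MAE.

Evaluation reports per-spectrum and artifact-averaged MAE, Pearson's r
(guarded against zero-variance inputs), t = r√(df/(1−r²)) with
df = n − 2, the two-sided Student-t p (also as log₁₀ p, switching to
the leading tail-expansion term where the CDF underflows double
precision), and the Fisher-z 95% CI. Fisher-z was adopted because it
reproduces published validation intervals from (r, d.f.) alone at
2-decimal rounding; its coverage at ρ = 0.5, n = 100 is verified by
simulation in the test suite.

## FTIR burn rules

Peak presence = topographic prominence / noise ≥ 3, where prominence is
the height of the (3-point-smoothed) local maximum above the straight
line between its two flanking minima inside the search window. This is
robust where a band rides the convex shoulder of a neighbor — the
630 cm⁻¹ window is bounded at [615, 640] cm⁻¹ precisely because the
phosphate ν4 603 cm⁻¹ shoulder encroaches from the left; a chord
through window-edge minima there would swallow the peak's flanks. A
maximum on the window edge is a shoulder, not a peak (prominence 0).
The SNR ≥ 3 threshold is a conventional detection limit; "prominent"
vs "small" peaks both map to present, and the threshold is exposed in
the configuration. Presence is monotone in the threshold by
construction.

Bone verdicts: *heated above 600 °C* iff the 630 cm⁻¹ call is present;
phosphate ν4 presence is reported as a bioapatite sanity flag (its
absence warns "not apatitic material" without suppressing the verdict).
Fragment color is not an input anywhere. The absence of a diagenetic
pathway to the 630 cm⁻¹ band is an assumption inherited from the bone
mineral literature, not something the code checks.

Sediment verdicts: phases are called from fingerprint bands — quartz
needs 1,084 and the 797/778 doublet; clay is identified from the
915 cm⁻¹ Al–OH deformation band (the 1,032 cm⁻¹ Si–O stretch is
routinely shadowed by the quartz 1,084 cm⁻¹ band in quartz-rich
sediments, which wet-lab density separation would otherwise resolve;
1,032 corroborates but is not required); calcite needs 1,420 plus at
least one of 874/713 (1,420 alone is ambiguous). The verdict *not
heated above 400 °C* requires both a clay call and surviving
structural water in 3,580–3,710 cm⁻¹; anything else is *indeterminate*
— the rule bounds temperature only when its premises hold. Note the
dehydroxylation onset (450 °C) sits above the 400 °C bound the verdict
names: the bound is deliberately conservative.

## Spatial and attribute tests

Moran's I uses row-standardized weights (inverse distance by default,
kNN optional); coordinates are planar meters within the excavation
grid; elevation is carried but not used in distance weights (assemblage
materials lie essentially at one elevation). Duplicate coordinates
receive a deterministic 1 cm jitter derived from the seed. Permutation
p-values use the add-one convention p = (1 + #{perm as extreme}) /
(1 + n_perm), so p > 0 always; temperatures are shuffled over fixed
coordinates (one-sided, high I), square labels are shuffled for the
within-square dispersion statistic (one-sided, low mean within-square
SD = constrained temperature ranges), attribute values are shuffled for
Spearman's ρ (two-sided) and type labels for the count-weighted
between-type variance of mean temperature (one-sided). These
transparent operationalizations stand in for what field reports often
assess visually; constant attributes and single-label type lists are
skipped with a notice.

## Pipeline

One global seed derives per-stage seeds by mixing with a CRC32 hash of
the stage name, so stages can be re-run in isolation and two runs from
one config are byte-identical in every output. The config is YAML with
one section per stage; unknown sections or keys are errors (fail
closed). Temperature estimation runs blind to the truth table — the
evaluation stage joins on sample id only. The demo assemblage (26
lithics × 27 replicates, 87 fauna with a 14-fragment burnt quota, 34
unheated quartz/clay sediments) exercises every stage at a scale that
runs in well under a minute.

## Known limitations

- The thermometer's held-out-source error depends on how far the
  held-out source's jittered response parameters sit from the training
  sources'; with few sources this is effectively a small-sample draw.
- The 630 cm⁻¹ rule is binary by design: it cannot distinguish 700
  from 1,000 °C, and near-onset exposures produce weak bands that a
  fixed SNR threshold will miss at sufficiently low instrument SNR.
- The sediment rule says nothing about clay-free samples, and
  dehydroxylation onsets vary with clay mineralogy; the default onset
  is a single representative value, configurable per run.
- Permutation tests assume exchangeability under the null; systematic
  estimation error that varies spatially (e.g. by flint source) would
  violate it.
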