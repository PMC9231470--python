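# pyrotrace

Spectroscopic detection of *hidden* fire exposure in archaeological
assemblages — heat that left no visible trace (no pot lids, discoloration,
warping or calcination) on lithics, faunal remains or sediments.

`pyrotrace` is aimed at archaeometrists and zooarchaeologists who want the
full inference chain behind "this assemblage was burnt" as tested,
reusable code:

1. **A deep-learning Raman paleothermometer for flint.** Heating flint
   irreversibly alters its UV Raman spectrum: the moganite band
   (~501 cm⁻¹) shrinks relative to the α-quartz main band (~465 cm⁻¹),
   the disordered/graphitic carbon D and G bands (~1,350/1,600 cm⁻¹)
   rise then fall, and the quartz band broadens. A 1-D convolutional
   network regresses exposure temperature T̂ (°C) from the spectrum,
   trained on sources heated to known temperatures; per-artifact
   estimates average the replicate spectra (27 per artifact by default),
   which demonstrably shrinks the mean absolute error
   MAE = mean|T̂ − T|. Validation reports Pearson's *r* with Student-t
   significance and a Fisher-z confidence interval,
   tanh(atanh r ± z₁₋α/₂/√(n−3)).
2. **Rule-based FTIR burn diagnostics.** For bone and tusk: a hydroxyl
   libration band at 630 cm⁻¹ appears only after the bone mineral
   recrystallizes at ≥ 600 °C, so its presence (SNR ≥ 3 above a local
   baseline) reads as *heated above 600 °C* — fragment color is
   deliberately not an input. For sediments: clay structural water
   (OH bands near 3,600–3,700 cm⁻¹) is lost irreversibly above
   ~400–500 °C, so a clay-bearing sediment that retains those bands was
   *not heated above 400 °C*.
3. **Spatial and attribute pattern tests.** Moran's I with a
   permutation null for spatial temperature clustering, within-square
   dispersion against shuffled square labels, and Spearman/permutation
   tests for size or type dependence of the estimates.
4. **A synthetic-spectrum generator** that emulates all of the above
   responses (pseudo-Voigt bands, logistic heat responses, per-source
   flint variability, instrument noise) with known latent temperatures,
   so the entire chain is testable end to end with no instrument data.

## Worked example

The demo re-enacts a small open-air Lower Paleolithic assemblage on
synthetic data: 26 lithic artifacts (27 Raman replicates each), 87
faunal fragments of which 14 were burnt past the hydroxylation onset,
and 34 associated sediment samples.

```bash
pyrotrace demo --seed 1 --outdir demo_run
```

prints (and archives under `demo_run/`):

```
pyrotrace demo run (seed 1)

lithic artifacts analyzed : 26
replicates per artifact   : 27
temperature range (est.)  : 153-743 C
faunal fragments analyzed : 87
  heated above 600 C      : 14
sediment samples analyzed : 34
  not heated above 400 C  : 34
Moran's I (temperatures)  : -0.086 (perm. p = 0.800)
validation MAE (spectrum) : 85.154 C
validation MAE (artifact) : 84.876 C
validation Pearson r      : 0.943863
```

Reading the numbers: the lithics were heated across a wide range
(153–743 °C) with no spatial autocorrelation (Moran's I ≈ −0.09,
permutation p = 0.8 — no hint of an in-place fire feature); exactly the
14 truly burnt fauna are called *heated above 600 °C*; all 34 sediments
retain clay structural water, bounding their history below 400 °C; and
against the withheld truth table the thermometer's per-spectrum MAE is
85 °C, improving to 84.9 °C after replicate averaging, with r = 0.94.

Each stage is also a library call (`pyrotrace.synth.simulate_site`,
`pyrotrace.thermometer.train_thermometer` / `estimate_artifact`,
`pyrotrace.ftir.classify_bone` / `classify_sediment`,
`pyrotrace.spatial.cluster_test` / `attribute_test`) and a CLI
subcommand (`simulate`, `train`, `estimate`, `ftir-classify`,
`spatial`, `evaluate`); runs are configured by a YAML file with one
section per stage and are byte-reproducible under a fixed config and
seed. See `docs/methods.md` for the models, parameters and their
defaults.

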