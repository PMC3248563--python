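# wormtriage

Quantification and triage machinery for genome-wide RNAi suppressor screens
of protein aggregation and proteotoxicity in *C. elegans* body-wall muscle.

Chronic expression of aggregation-prone proteins — expanded polyglutamine
(polyQ) tracts fused to YFP, or mutant SOD1^G93A — produces fluorescent foci
and a measurable motility defect in nematode muscle. A suppressor screen
knocks down one gene at a time by feeding RNAi and asks, stage by stage,
which knockdowns (i) reduce foci counts, (ii) do so across reporters,
(iii) also restore animal motility, and (iv) rescue the misfolding phenotypes
of endogenous temperature-sensitive (TS) mutant proteins. `wormtriage`
implements every quantitative step of that pipeline for screen analysts:

* **Video tracking and BLPS** (`wormtriage.imaging`, `wormtriage.tracking`) —
  de-flickering, temporal-maximum background estimation, Otsu binarization,
  greedy nearest-neighbour blob linking, and the motility statistic
  *body lengths per second*:

  `BLPS = path_length / body_length / track_duration`

  with body length estimated as the median skeleton longest-path over the
  track's frames.
* **Foci counting and suppression calls** (`wormtriage.foci`) — local
  background (median filter) + k·σ detection with the assay's physical size
  gate (area ≥ 7 µm² or caliper ≥ 3 µm), and the parameterized positivity
  rule: a gene scores positive when more than `f` of the treated animals show
  at least an `r` reduction in foci versus the EV-control mean (genome screen:
  f = 50%, r = 50%; strong hits: ≥ 60% reduction in ≥ 75% of animals;
  counter-screens: strictly > 25% reduction).
* **FRAP solubility analysis** (`wormtriage.frap`) — double-normalized
  relative fluorescence intensity RFI(t) = (T₀·I(t))/(T(t)·I₀), empirical
  recovery plateau, mobile fraction
  `f_m = (plateau − RFI_postbleach)/(1 − RFI_postbleach)`, and
  soluble / intermediate / immobile calls.
* **Expression controls** (`wormtriage.expression`) — comparative-CT qPCR
  fold changes (fold = 2^(−ΔΔCT)) and western YFP/tubulin band ratios as
  percent of control with a Student t-test "unchanged" verdict.
* **The triage tree** (`wormtriage.triage`) — genome screen → soluble-reporter
  artifact filter → cross-reporter Class A/B split → SOD1 co-suppression →
  wild-type motility exclusion → polyQ motility classification → TS rescue,
  with functional-class tallies and chi-square enrichment.
* **Synthetic data with ground truth** (`wormtriage.simulate`) — seeded
  generators for worm videos, foci images, FRAP traces, and planted screen
  outcome tables, so every stage is testable without any external data.

## Worked example

Run the full decision tree on the packaged reference screen scenario
(planted outcome tables, fixture seed 1002438):

```python
from wormtriage import default_screen_fixture, run_triage

dataset, truth = default_screen_fixture()
result = run_triage(dataset)
print(result.stage_counts)
print(result.class_percentages)
print(sorted(result.core_modifiers))
```

prints

```
{'q35_positives': 151, 'class_a': 88, 'sod1_common': 63, 'wt_motility_pass': 55,
 'toxicity_suppressors': 23, 'core_modifiers': 9}
{'suppress': 42, 'no_change': 36, 'enhance': 22}
['C45G3.4', 'F43G9.1', 'R05D11.4', 'T22B11.5', 'Y110A7A.8',
 'ZK430.7', 'gei-11', 'let-607', 'ucr-2.3']
```

i.e. 151 genome-screen suppressors funnel down to 88 Class A modifiers
(also effective on the longer polyQ reporter), 63 of which co-suppress
mutant SOD1 aggregation; 33 of the 88 alter wild-type motility on their own
and are excluded; of the remaining 55, 42% also rescue the polyQ motility
defect (the 23 toxicity suppressors), and 9 of those rescue at least one of
four TS folding-sensor strains — the core proteostasis modifiers.

The same pipeline runs from the shell:

```bash
wormtriage simulate screen --seed 1002438 --out scratch/screen
wormtriage triage --records scratch/screen/screen_dataset.json --out scratch/triage.json
wormtriage simulate video --seed 7 --out scratch/video --speed-blps 0.15
wormtriage track --stack scratch/video/video.tif --out scratch/tracks.csv
```

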