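# mitoaxon

Quantification of axonal mitochondrial function, morphology and
trafficking in two-channel *in vivo* confocal imaging of the mouse
spinal cord, built for the relapsing–remitting EAE
(experimental autoimmune encephalomyelitis) setting, together with a
calibrated synthetic-scene generator that emulates six disease stages
(naive, adjuvant control, asymptomatic, onset of deficits, remission,
relapse).

It is aimed at neuroimaging groups who label axonal mitochondria with
CFP (Thy1-CFP/COX8A "MitoMouse") and report membrane potential with the
cationic dye TMRM: CFP shows every axonal mitochondrion, TMRM only the
polarized (functional) ones.

## What it computes

For still fields (CFP + TMRM):

- CFP segmentation of ~0.5 µm-wide capsule-shaped mitochondria; length
  is the size measure, estimated from integrated fluorescence so it
  stays unbiased down to the resolution limit;
- polarization classes — depolarized ⇔ no detectable TMRM, i.e. object
  TMRM ≤ background + 2 robust SD — and depolarized fractions by count
  (within the 1.5–2.5 µm "small" class) and by mass;
- length histograms (0.5 µm bins) with the named small (1.5–2.5 µm) and
  long (6–9 µm) classes; mitochondrial mass as integrated length per
  100 µm of axon and as CFP⁺ area fraction;
- the **index of axonal mitochondrial capacity**,

  `index = (combined length of TMRM⁺ mitochondria) × (mean TMRM intensity metric)`,

  with the mean ratiometric TMRM/CFP amplitude as the default metric
  and the coefficient-of-variance form (sd/mean over object means) as
  an alternative;
- the axonal membrane-potential proxy: mean axoplasmic TMRM
  (mitochondria excluded) over the non-fluorescent blood in a nearby
  vessel;
- per-field infiltrating-cell counts (TMRM-bright perivascular somata).

For 50-frame / 98.5 s time-lapses:

- per-axon tracking with occlusion-aware linking and kymograph-style
  repair of crossing artifacts;
- motile density per 100 µm of axon (motile ⇔ net displacement ≥ 2 µm),
  rostral/caudal balance, and speed (path length / elapsed time).

Statistics: two-way ANOVA (stage × mouse) with Bonferroni post-hoc
contrasts and D'Agostino–Pearson normality checks, and per-field OLS
regressions of any metric on the infiltrate count (r², p, slope).

The synthetic generator is first-class, tested code: it renders fields
and movies with exact ground truth and its six stage configurations are
locked by an internal calibration so that ground-truth statistics hit
the published stage endpoints (depolarized fractions, intensity
decrements, capacity ratios, motile densities, +104% small-mito count,
infiltrate coupling r²) to within 1%.  See `docs/methods.md` for the
model and its limitations.

## Worked example

```python
from mitoaxon import scenario_defaults
from mitoaxon.simulate import generate_field
from mitoaxon.pipeline import analyze_field

config = scenario_defaults("onset")          # first day of deficits
field, truth = generate_field(config, seed=7)
objects, labels, summary = analyze_field(field, truth.axon_y_um,
                                         truth.vessel_mask)
```

prints, via the summary dict:

```
objects:              157
median length:        1.81 um
depolarized mass:     42.7 %
small-class depolar.: 52.2 %
mass per 100 um axon: 24.2 um
capacity index:       8216
axonal TMRM ratio:    3.73
infiltrating cells:   12
```

This is one onset field: heavily fragmented mitochondria (median
1.8 µm against ~3.3 µm in controls), about half of the small class and
~40% of total mitochondrial mass depolarized, a depressed capacity
index, a lowered axoplasm/blood TMRM ratio, and a perivascular
infiltrate.  `objects` is a tidy DataFrame (one row per mitochondrion
with length, intensities, polarization class) ready for the statistics
layer.

The same flows are scriptable from the shell:

```sh
mitoaxon simulate --stage onset --seed 7 --fields 12 --out sim/
mitoaxon quantify sim/*.tif --out summaries.csv
mitoaxon simulate --stage naive --seed 1 --movie --out mov/
mitoaxon track mov/*.tif --out tracks.csv
mitoaxon reproduce-paper --seed 1        # endpoint table, ~2 min
```

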