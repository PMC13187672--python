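# darkinhib

A meta-analysis toolkit for **Rubisco dark inhibition** across flowering
plants.

Rubisco, the CO₂-fixing enzyme of photosynthesis, loses *total activity* in
many species after a dark or low-light period because inhibitory
sugar-phosphates (chiefly 2-carboxy-D-arabinitol 1-phosphate, CA1P) bind the
carbamylated active site. The strength of this **dark inhibition** is
standardised as

```
DI = 1 − (dark-adapted total activity / light-adapted total activity)
```

expressed in percent (×100). DI is unit-free, can exceed 90% in species such
as *Phaseolus vulgaris*, sits near zero in wheat and many C4 grasses, and is
negative when daytime inhibitors depress the light-adapted activity instead.

The package is for photosynthesis researchers and comparative biologists who
want to (a) standardise published light/dark activity data into DI, (b)
derive categorical inhibition levels from the multimodal structure of the
species-level DI distribution, (c) compare taxonomic groups
nonparametrically, and (d) project the results onto a phylogeny. It ships a
curated summary table of 157 species (14 orders) as a packaged fixture, plus
a synthetic-data generator that emulates the statistical structure of the
literature so every stage is testable without downloads.

## What it computes

* **Dark-inhibition statistic and QC** — per-genotype DI from light/dark
  activity pairs; species-level aggregation (unweighted mean, sample SD);
  assay-method filtering; covariate screens (OLS trend, DerSimonian–Laird
  random-effects meta-regression, Kruskal–Wallis).
* **Multimodality machinery** — Hartigan & Hartigan dip statistic (exact
  greatest-convex-minorant/least-concave-majorant algorithm) with a
  Monte-Carlo test; Silverman critical-bandwidth tests with variance-rescaled
  smoothed bootstrap; univariate Gaussian-mixture EM with BIC selection; KDE
  mode/antimode extraction with Sheather–Jones or rule-of-thumb bandwidths.
  Category thresholds are the antimodes between substantive density peaks.
* **Classification and comparison** — level assignment (left-closed
  intervals on the published cutpoints 18/44/77), count tables,
  Kruskal–Wallis + Dunn post-hoc with Holm adjustment and compact letter
  displays, with a minimum group size of five.
* **Phylogeny annotation** — genus-level aggregation, level colouring and
  iTOL dataset export; coverage statistics against the 64 flowering-plant
  orders.

## Worked example

```python
import numpy as np
from darkinhib import load_table1_fixture
from darkinhib.classify import level_counts, classification_concordance
from darkinhib.modality import PAPER_DEFAULT, derive_thresholds

ds = load_table1_fixture()
print(level_counts(ds.summaries)["count"].to_dict())
# {'low': 57, 'moderate': 45, 'high': 45, 'very_high': 10}

d = derive_thresholds(np.array(ds.species_means()))
print(d.n_main_modes, d.thresholds.cutpoints)
# 4 (18.0, 45.0, 76.0)

rep = classification_concordance(ds.summaries, PAPER_DEFAULT)
print(rep.n_agree, rep.disagreements[0][0])
# 156 Melilotus albus
```

The species-mean DI distribution shows four substantive density peaks
(≈ 1, 39, 54 and 86%); the valleys between them re-derive the published
category boundaries (18, 44, 77) to within a few percent. Re-classifying
every species from its printed mean agrees with the printed level label for
156 of 157 species; the single disagreement (*Melilotus albus*, printed mean
46 labelled moderate) is a documented inconsistency of the source table.

Narrative scripts in `examples/` cover each capability: fixture summary,
threshold derivation, group comparison, synthetic-data recovery and tree
annotation. A thin CLI (`darkinhib ingest|qc|summarize|modality|classify|
compare|tree|simulate|run`) wraps the same functions for shell use.

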