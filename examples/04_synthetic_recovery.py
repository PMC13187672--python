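"""Simulate a literature-like dataset and recover its generating structure.

The generator draws species means from a four-component Gaussian mixture
(weights matching the published level proportions) with taxonomic clustering
and genotype-level replicate noise, then the analysis pipeline re-derives
the component boundaries from the simulated observations.
"""
import numpy as np

from darkinhib.core import aggregate_species
from darkinhib.modality import derive_thresholds
from darkinhib.synth import SyntheticConfig, generating_antimodes, simulate_observations

cfg = SyntheticConfig(seed=4)
print("generating antimodes:", np.round(generating_antimodes(cfg), 2))

ds, truth = simulate_observations(cfg)
print(f"simulated {len(ds.observations)} observations for {cfg.n_species} species")

summaries = aggregate_species(ds)
values = np.array([s.mean_di_percent for s in summaries])
d = derive_thresholds(values)
print(f"recovered {d.n_main_modes} substantive modes")
print("recovered cutpoints:", d.thresholds.cutpoints if d.ok else None)
# With the default calibration the pipeline finds four modes and cutpoints
# within a few percent of the generating antimodes (about 19, 44 and 74%).
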