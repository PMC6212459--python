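"""Effect of the mitotic phenotype switch on the primary scenario.

With probability p_mut = 0.5 a dividing cell redraws its adhesion
phenotype uniformly from the allowed set and passes it to both
daughters.  Switching flattens the phenotype frequencies and, for the
primary cell line, reduces the final population and expansion relative
to fixed inheritance.
"""

import glioinvade as gi
from glioinvade.experiments import switch_study
from glioinvade.model_core import LatticeGeometry

base = gi.primary_config(
    geometry=LatticeGeometry(side_mm=2.4, site_um=20.0),
    initial_radius_um=140.0,
    t_max_h=72.0,
    seed=5,
)
report = switch_study("primary", p_mut=0.5, n_reps=4, base_config=base)

print(f"Compared at t = {report.time_h:.0f} h (switch off -> on, 4 paired replicates):")
for metric in ("n_cells", "invasive_radius_um", "compactness", "sparseness"):
    print(f"  {metric:22s} {report.off_means[metric]:10.2f} -> {report.on_means[metric]:10.2f}")
print(f"  max |freq - uniform| over allowed set: {report.max_freq_deviation:.4f}")
print(
    "\nSwitching homogenises the phenotype composition (small deviation from "
    "uniform); the self-organised enrichment of particular adhesion classes "
    "seen without switching is lost."
)
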