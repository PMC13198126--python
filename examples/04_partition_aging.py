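"""Partition an esterified FA among lipid classes and compare groups.

After the three-tier quantification, each esterified FA is apportioned
among lipid sinks by weighting species amounts with their saponifiable
acyl multiplicity.  Here FA 18:1 is partitioned per sample in a simulated
aging study whose aged group doubles the 18:1-bearing TGs: the TG share of
the esterified 18:1 pool rises at the expense of the phospholipid sinks,
and the per-condition fractions are combined into a flow table with deltas
and t-test p values.
"""

from lipidtiers import (
    default_spec,
    esterified_from_subtraction,
    load_is_map,
    load_panel,
    partition_flows,
    partition_fractions,
    quantify_by_internal_standard,
    render_peak_areas,
    simulate_tissue,
)
from lipidtiers.synthdata import quantify_lipidome_table

spec = default_spec(seed=11, noise_sd=0.05)
truth = simulate_tissue(spec)
tables = render_peak_areas(truth, spec)
panel, is_map = load_panel(), load_is_map()

free = quantify_by_internal_standard(tables["C"], panel, is_map)
total = quantify_by_internal_standard(tables["B"], panel, is_map)
ledger = esterified_from_subtraction(free, total)
lipidome = quantify_lipidome_table(tables["A"], spec.lipidome_is_pmol)

parts = {}
for group in ("young", "old"):
    sel_lip = lipidome[lipidome["sample_id"].str.startswith(group)]
    sel_led = ledger[ledger["sample_id"].str.startswith(group)]
    parts[group] = partition_fractions(
        sel_lip, sel_led, "FA 18:1 n-9", denominator_mode="tier-derived"
    )

flow = partition_flows(parts)
print("fraction of the esterified FA 18:1 pool explained by each sink:")
print(
    flow[["condition", "sink", "mean_fraction", "n", "delta", "p_value"]]
    .to_string(index=False, float_format="%.4f")
)
print()
print("the TG share rises in the aged group (positive delta, small p) while")
print("the PC/PI/PS shares shrink: excess 18:1 is preferentially directed")
print("into neutral-lipid storage.  Sphingolipids (SM, Cer) appear in no")
print("sink because their N-acyls resist alkaline hydrolysis.")
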