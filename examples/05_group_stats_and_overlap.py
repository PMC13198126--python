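"""Differential analytes per tissue and their exclusive overlaps.

Runs the two-group comparison (Student's t, p < 0.05, fold change of group
means) on two simulated tissues with partly shared aging effects, then
summarizes which significant analytes are tissue-specific versus conserved
using UpSet-style exclusive intersection counts.
"""

from lipidtiers import (
    SimulationSpec,
    exclusive_intersections,
    group_compare,
    load_is_map,
    load_panel,
    quantify_by_internal_standard,
    render_peak_areas,
    simulate_tissue,
    volcano_table,
)

panel, is_map = load_panel(), load_is_map()
free = (("FA 16:0", 50.0), ("FA 17:1", 4.0), ("FA 18:1 n-9", 60.0),
        ("FA 18:2", 25.0), ("FA 20:4 n-6", 12.0), ("FA 22:6", 8.0))

effects = {
    "gastrocnemius": (("old", "FA 17:1", 2.0), ("old", "FA 18:2", 1.8),
                      ("old", "FA 18:1 n-9", 1.5)),
    "soleus": (("old", "FA 18:1 n-9", 1.5), ("old", "FA 20:4 n-6", 1.6)),
}

sig_sets = {}
for i, (tissue, eff) in enumerate(effects.items()):
    spec = SimulationSpec(seed=20 + i, free_amounts=free, lipidome=(),
                          group_effects=eff, noise_sd=0.05)
    tables = render_peak_areas(simulate_tissue(spec), spec)
    amounts = quantify_by_internal_standard(tables["C"], panel, is_map)
    comp = group_compare(amounts, reference="young")
    sig_sets[tissue] = set(comp.loc[comp["significant"], "analyte"])
    print(f"--- {tissue}: significant age effects (alpha 0.05) ---")
    v = volcano_table(comp)
    print(
        v[v["significant"]][["analyte", "fold_change", "log2_fold_change", "p_value"]]
        .to_string(index=False, float_format="%.4f")
    )
    print()

summary = exclusive_intersections(sig_sets)
print("exclusive overlap of significant analytes (UpSet convention):")
for pattern, count in sorted(summary.counts.items(), key=lambda kv: -kv[1]):
    label = " & ".join(sorted(pattern))
    members = ", ".join(sorted(summary.members[pattern]))
    print(f"  only in {label}: {count}  ({members})")
print()
print("conserved changes (both tissues) point to shared aging biology —")
print("here the injected FA 18:1 effect; tissue-specific sets reflect the")
print("distinct effect panels injected per tissue.")
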