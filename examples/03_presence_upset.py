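"""Presence/absence intersection analysis (UpSet counts).

Calls a lipid present in a culture when its replicate-mean relative
abundance reaches 0.01% of total lipids, then counts species per exact
group-membership pattern — the numbers behind an UpSet plot, including
how many species the symbiont shares with (i.e. likely recruits from)
its host.
"""

import halolipidome as hl
from halolipidome.composition import upset_counts_frame
from halolipidome.simulate import INTERNAL_STANDARD_ID

design = hl.default_design(seed=1, abundance_sigma=0.0, mz_jitter_sd=0.0,
                           spurious_peak_rate=0.0)
table, truth = hl.simulate_lipidome(design)
merged, _ = hl.merge_adducts(hl.correct_recovery(table, INTERNAL_STANDARD_ID))

profile = hl.relative_abundance(merged)
presence = hl.call_presence(profile, threshold=1e-4)

for group in presence.columns:
    print(f"{group:>10s}: {int(presence[group].sum())} lipid species")
print()
print(upset_counts_frame(presence).to_string(index=False))
# The pattern counts partition the species present anywhere; the
# host&coculture row counts species the symbiont never takes up.
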