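"""Curate the packaged Fascin active set and print its potency ranking.

Loads the 25 transcribed binding-site-2 inhibitors, keeps records with a
determined affinity <= 100 µM, and ranks them by their most potent
available value (min of IC50 and Kd).
"""

from screenmd import curate, load_reference_actives

curated = curate(load_reference_actives())
frame = curated.to_frame().sort_values("bioactivity_rank")

print(frame[["id", "ic50", "kd", "cluster", "bioactivity_rank", "loa", "tod"]]
      .to_string(index=False))
print(
    f"\n{len(curated)} records across {len(curated.clusters)} chemotype clusters."
    "\nbioactivity_rank 1 = most potent; loa is the same potency in mol/L;"
    "\ntod says whether that value came from an IC50 or a Kd measurement."
)
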