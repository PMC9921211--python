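"""Score-list benchmarking: pROC-AUC, ROC-AUC and enrichment factors.

Simulates a 25-active / 750-decoy docking score list at three levels of
active/decoy separation and prints the screening metrics for each.
"""

from screenmd import ScoreSimSpec, enrichment_factor, proc_auc, roc_auc, simulate_scores

for label, mu_active in [("perfect", -190.0), ("good", -105.0), ("random", -90.0)]:
    lib = simulate_scores(
        ScoreSimSpec(
            n_actives=25, n_decoys=750,
            mu_active=mu_active, mu_decoy=-90.0, sigma=8.0, seed=1,
        )
    )
    proc = proc_auc(lib)
    ef1 = enrichment_factor(lib, 0.01)
    print(
        f"{label:>8}: pROC-AUC={proc.auc:5.3f}  ROC-AUC={roc_auc(lib):5.3f}  "
        f"EF1%={ef1.ef:5.2f} ({ef1.bioactives_subset}/{ef1.n_subset} actives in top 1%)"
    )

print(
    "\npROC-AUC ~0.434 means random ranking; EF1% = 31 is the ceiling for"
    "\n25 actives in 775 compounds (every top-1% entry is an active)."
)
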