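"""Head-to-head: likelihood-ratio FDR test vs Benjamini-Hochberg.

Runs three replicates of a mid-power scenario (p1=0.8, mu=3) on an 80 x 80
grid and prints averaged realized FDR and FNDR for both methods.
"""

from lrfdr import SimConfig, run_study

cfg = SimConfig(p1=0.8, mu=3.0, grid=(80, 80), n_reps=3)
study = run_study([cfg], methods=("lr_one", "bh"), master_seed=7)

print(study.summary.to_string(index=False))
print()
for method, label in (("lr_one", "LR-FDR"), ("bh", "BH-FDR")):
    fdr = study.mean_rate(cfg.name, method, "fdr")
    fndr = study.mean_rate(cfg.name, method, "fndr")
    print(f"{label}: averaged FDR {fdr:.4f}, averaged FNDR {fndr:.4f}")
print("\nBoth methods respect the 0.05 FDR target, but BH lands well below")
print("it (conservative) and pays with a much larger false non-discovery")
print("rate; the likelihood-ratio test spends the full FDR budget and")
print("misses far fewer true effects.")
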