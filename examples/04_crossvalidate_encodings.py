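"""Compare the three window encodings by 5-fold cross-validation.

Runs the balanced window-19 pipeline on one synthetic dataset and reports
the threshold-scanned operating point (minimum |Sen - Spe|) plus ROC AUC
for composition (CPP), one-hot (BPP) and physico-chemical (PPP) profiles —
both with pattern-level folds (the classical protocol) and with
antigen-held-out folds (no antigen contributes windows to two folds).
"""

from epiwin import (
    SimulationConfig,
    assemble_set,
    cross_validate,
    generate_all_patterns,
    generate_antigens,
    parse_svmlight_params,
)

antigens = generate_antigens(SimulationConfig(n_antigens=80, seed=17))
pset = assemble_set(generate_all_patterns(antigens, 19), "balanced", seed=18)
print(f"{len(pset.patterns)} balanced patterns "
      f"({pset.counts()[0]} pos / {pset.counts()[1]} neg)\n")

PARAMS = {
    "cpp": "t 2 g 0.01 j 1 c 1",
    "bpp": "t 2 g 0.001 j 1 c 10",
    "ppp": "t 2 g 0.00001 j 1 c 10",
}

for split in ("pattern", "antigen"):
    print(f"--- {split}-level folds ---")
    for enc, params in PARAMS.items():
        r = cross_validate(pset, enc, 19, parse_svmlight_params(params),
                           k=5, split_unit=split, seed=19)
        m = r.mean_row
        print(f"{enc.upper()}: Thr*={r.selected_threshold:+.1f}  "
              f"Sen={m.sen:5.1f}  Spe={m.spe:5.1f}  Acc={m.acc:5.1f}  "
              f"MCC={m.mcc:.3f}  AUC={r.pooled_auc:.3f}")
    print()

print("Composition dominates under the pattern-level protocol partly because "
      "it is insensitive to the one-residue shifts between overlapping windows "
      "of a patch that fall in train and test folds. Antigen-held-out folds "
      "remove that leakage: every encoding drops, and at this training size "
      "the ordering can shift.")
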