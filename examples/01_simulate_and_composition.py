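"""Generate synthetic labeled antigens and compare epitope vs background
amino-acid composition.

Epitope patches are tilted toward the charged/polar residues preferred at
antibody interfaces (C, D, E, K, N, Q, R, W, Y); the report shows the
per-class frequencies the composition-based predictor exploits.
"""

from epiwin import SimulationConfig, composition_report, generate_antigens
from epiwin.simulate import ENRICHED_RESIDUES

cfg = SimulationConfig(n_antigens=50, seed=1)
antigens = generate_antigens(cfg)

n_pos = sum(sum(a.labels) for a in antigens)
n_tot = sum(len(a) for a in antigens)
print(f"{len(antigens)} antigens, {n_tot} residues, "
      f"{n_pos} interacting ({100 * n_pos / n_tot:.1f}%)")

report = composition_report(antigens)
enriched = report.loc[list(ENRICHED_RESIDUES)]
print(f"\nenriched-set frequency: interacting {enriched['interacting'].sum():.3f} "
      f"vs background {enriched['non_interacting'].sum():.3f}")
print("\nper-residue frequencies (interacting vs non-interacting):")
print(report.round(3).to_string())
print("\nThe interacting class carries ~0.25 extra probability mass on the "
      "enriched residues — the local-composition signal the method predicts from.")
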