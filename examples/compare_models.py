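"""Whole-brain AnnaK-versus-Nearest-Neighbors comparison.

Thirty nodes all carry AnnaK coupling; both models are fit at every node
with one shared permutation stream, then the node-averaged Fisher-Z
difference decides which model describes the cohort better.
"""

import numpy as np

import isrsa

spec = isrsa.SimSpec(
    n_subjects=60, n_nodes=30, n_timepoints=600,
    node_models=("annak",) * 30, coupling=(0.8,) * 30, seed=42,
)
behavior = isrsa.generate_behavior(spec)
tc = isrsa.generate_timecourses(behavior, spec)

rng = np.random.default_rng(1)
result = isrsa.run_all_nodes(
    isrsa.pairwise_isc(tc), tc.node_ids, behavior["score"].to_numpy(),
    ["annak", "nn"], isrsa.control_design(behavior), n_perm=1000, rng=rng,
)
for model in ("annak", "nn"):
    sub = result.table[result.table["model"] == model]
    fw = isrsa.familywise_count_test(int(sub["sig_uncorrected"].sum()),
                                     len(tc.node_ids), 0.05, 10_000, rng)
    print(f"[{model:>5}] median rho {sub['rho'].median():+.3f}; "
          f"{fw.observed_count}/{len(tc.node_ids)} nodes p<.05, "
          f"familywise p = {fw.p_familywise:.4g}; "
          f"{int(sub['sig_corrected'].sum())} survive Holm")

mc = isrsa.model_comparison(result)
print(f"mean Fisher-Z diff (annak - nn): {mc.mean_z_diff:+.3f} "
      f"(rho scale {mc.rho_scale_diff:+.3f}), p = {mc.p_two_sided:.4g}")
# A positive difference with small p: the AnnaK model fits this cohort
# better across the brain — exactly what was planted.
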