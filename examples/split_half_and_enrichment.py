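"""Split-half consistency and network enrichment of significant nodes.

Half the nodes carry AnnaK coupling and belong to a "motor" network; the
split-half analysis checks that the spatial profile of model fit
replicates across disjoint cohorts, and the enrichment test asks whether
corrected-significant nodes concentrate in one network.
"""

import numpy as np
import pandas as pd

import isrsa

spec = isrsa.SimSpec(
    n_subjects=60, n_nodes=40, n_timepoints=600,
    node_models=("annak",) * 20 + ("null",) * 20,
    coupling=(0.9,) * 20 + (0.0,) * 20, seed=5,
)
behavior = isrsa.generate_behavior(spec)
tc = isrsa.generate_timecourses(behavior, spec)

sh = isrsa.split_half(tc, behavior, "annak", np.random.default_rng(2))
print(f"split-half consistency r (across {len(tc.node_ids)} nodes): "
      f"{sh.consistency_r:.3f}")

result = isrsa.run_all_nodes(
    isrsa.pairwise_isc(tc), tc.node_ids, behavior["score"].to_numpy(),
    ["annak"], isrsa.control_design(behavior), n_perm=1000,
    rng=np.random.default_rng(3),
)
networks = pd.Series(["motor"] * 20 + ["default"] * 20, index=tc.node_ids)
flags = pd.Series(result.table["sig_corrected"].to_numpy(), index=tc.node_ids)
print(isrsa.network_enrichment(flags, networks).to_string(index=False))
# High consistency r: the coupled-vs-null node profile replicates across
# halves.  The motor network holds nearly all corrected-significant nodes,
# far above its chance expectation, hence its tiny hypergeometric p.
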