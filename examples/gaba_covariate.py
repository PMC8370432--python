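"""Does adding the MRS GABA covariate improve the between-subject model?

Fits the second-level model over the GABAergic synapses with and without
the (standardized) GABA column, compares free energies, and reports the
GABA interaction effects — then shows that permuting GABA across subjects
destroys the advantage.
"""

import numpy as np

from dcmerf import CohortSpec, PipelineRun, RunConfig

run = PipelineRun(RunConfig(outdir="scratch/example_gaba", seed=1,
                            cohort=CohortSpec(fidelity="posterior")))
run.simulate()
run.fit()
res = run.gaba()

labels = res["comparison"]["labels"]
probs = res["comparison"]["probability"]
print(f"delta F (with - without GABA): {res['delta_F']:+.1f} nats")
for lab, p in zip(labels, probs):
    print(f"  P({lab}) = {p:.3f}")
print("\nGABA effects with Pp > 0.9:")
t = res["gaba_effects"]
print(t[t["Pp"] > 0.9].to_string(index=False))

shuffled = [run.gaba(shuffle_seed=s)["delta_F"] for s in range(5)]
print(f"\nafter permuting GABA across subjects, median delta F = "
      f"{np.median(shuffled):+.1f} nats — the covariate's contribution "
      "is specific, not an artefact of extra columns.")
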