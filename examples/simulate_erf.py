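"""Simulate event-related fields from the six-source auditory hierarchy.

Builds the default network (bilateral A1, STG, IFG; six populations per
source), drives it with the Gaussian auditory/expectancy bump (peak 60 ms)
and prints where and when each source's ERF peaks.
"""

import numpy as np

from dcmerf import (ERFModel, NetworkSpec, ParameterSet,
                    build_parameter_priors)

net = NetworkSpec()
model = ERFModel(net, condition=False)
prior = build_parameter_priors(net)

# prior-mean simulation (theta = 0)
ds = model.simulate_dataset(prior.parameter_set())
t = ds.time_ms
print("source   peak (a.u.)   latency (ms)")
for i, src in enumerate(ds.sources):
    j = np.argmax(np.abs(ds.erf[i]))
    print(f"{src:6s}   {ds.erf[i, j]:+9.2f}   {t[j]:8.0f}")

# doubling deep-interneuron tonic inhibition damps the late deflections
theta = ParameterSet(prior.names, np.zeros(prior.p))
theta.values[list(prior.names).index("tonic:di")] = np.log(2.0)
ds2 = model.simulate_dataset(theta)
change = 100 * (np.abs(ds2.erf).max() / np.abs(ds.erf).max() - 1)
print(f"\nwith tonic:di doubled, the peak ERF changes by {change:+.1f}% — "
      "the laminar inhibitory parameters shape the measurable response.")
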