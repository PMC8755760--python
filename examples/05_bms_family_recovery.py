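"""Random-effects BMS over the 73-model connectivity space.

Simulates four-node BOLD series from the parallel / bidirectional-
interaction / preferred-targets model for 12 subjects, scores all 73
models with the least-squares + BIC evidence proxy, and runs the staged
family comparisons (direction -> pathway -> interaction -> targets).
"""

import numpy as np

from stopthink.dcm import (
    EvidenceMatrix,
    build_model_space,
    evidence_proxy_fit,
    staged_family_comparisons,
)
from stopthink.synth import make_task_inputs, simulate_network_timeseries
from stopthink.synth.network import hrf_kernel

space = build_model_space()
true_model = space.by_id(12)
print(f"model space: {len(space)} models; generating from model "
      f"{true_model.id} ({true_model.pathway}, {true_model.interaction} "
      f"interaction, {true_model.targets} targets)")

inputs = make_task_inputs(512)
kernel = hrf_kernel()
log_ev = np.zeros((12, len(space)))
for s in range(12):
    series = simulate_network_timeseries(true_model, inputs=inputs,
                                         n_scans=512, seed=51 + s)
    for m in space.models:
        log_ev[s, m.id] = evidence_proxy_fit(series, m, inputs,
                                             hrf_kernel=kernel)

ev = EvidenceMatrix(log_ev, [m.id for m in space.models])
stages = staged_family_comparisons(ev, space, n_samples=100_000, seed=51)
for name in ("direction", "pathway", "interaction", "targets"):
    res = stages[name]
    ep = ", ".join(f"{l} = {p:.3f}" for l, p in
                   zip(res.labels, res.exceedance_prob))
    print(f"  {name:12s} exceedance: {ep}")
best = int(np.argmax(stages["all_models"].exceedance_prob))
print(f"  all 73 models: winner id {stages['all_models'].labels[best]} "
      f"(EP = {stages['all_models'].exceedance_prob[best]:.3f})")
print("Exceedance = probability a family is more frequent in the "
      "population than the alternatives; the planted family should win "
      "every stage.")
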