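"""Quantify structural robustness with Newman–Ziff percolation.

Dismantles one network three ways — random edge failure, random node
failure, targeted (highest-degree-first) attack — and prints the two
robustness summaries: f1% (removable fraction before the giant component
drops below 1% of N; larger = more robust) and R (area under the
relative giant-component curve; average connectivity over the whole
process).  Susceptibility peaks locate the percolation transition(s).
"""

import numpy as np

from nncrn import (
    GeneratorSpec,
    ensemble_curves,
    erdos_renyi,
    summarize_robustness,
)

g = erdos_renyi(GeneratorSpec.er(2000, 5.0, seed=9))
print(f"ER network: N={g.n_nodes} M={g.n_edges}  (bond threshold 1/<k> = 0.2)")

for mode in ("random_edge", "random_node", "targeted_degree"):
    curve = ensemble_curves(g, mode, 100, np.random.default_rng(10))
    summ = summarize_robustness(curve, x=0.01)
    peaks = [
        f"p*={pk.p_star:.3f}"
        for pk in sorted(summ.peaks, key=lambda q: -q.chi_star)[:1]
    ]
    print(
        f"{mode:16s}: f1% = {summ.f_x:.3f}  R = {summ.R:.3f}  "
        f"dominant chi peak {peaks[0] if peaks else 'n/a'}"
    )
print("Targeted attack needs far fewer removals than random failure,")
print("and the chi peak under edge failure sits near the 0.2 threshold.")
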