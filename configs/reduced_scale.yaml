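# Reduced-scale study profile: runs in minutes on a laptop.
# Couplings are in units of the edge count M.
generator: {family: erdos_renyi, n: 2000, mean_degree: 5.0}
j1_values: [-2.0, 0.0, 2.0]
j2_values: [-2.0, 0.0, 2.0]
n_realizations: 20
rewiring_sweeps: 200
percolation_modes: [random_edge, random_node, targeted_degree]
percolation_runs: 100
threshold_x: 0.01
master_seed: 1
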