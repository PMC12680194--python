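# Full study profile. LONG-RUNNING: 25 coupling cells x 100 realizations
# at N = 20000 with 1e4*M proposals per chain — budget days of CPU time.
generator: {family: erdos_renyi, n: 20000, mean_degree: 5.0}
j1_values: [-2.0, -1.0, 0.0, 1.0, 2.0]
j2_values: [-2.0, -1.0, 0.0, 1.0, 2.0]
n_realizations: 100
rewiring_sweeps: 10000
percolation_modes: [random_edge, random_node, targeted_degree]
percolation_runs: 100
threshold_x: 0.01
master_seed: 1
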