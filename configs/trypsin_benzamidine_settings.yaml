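# Published analysis settings for the Trypsin-Benzamidine study, recorded
# for documentation: the underlying 149.1 us MD dataset is not deposited,
# so this config documents parameters rather than enabling a rerun.
# Frame interval of the original data: 100 ps; MSM lag 30 ns = 300 frames.
input_mode: features
input_paths: []          # residue-group distance CSVs (not available)
tica_lag: 300
n_components: 5          # the five slowest TICA components
dmin: 0.25               # sized to yield on the order of 139 initial microstates
split_cutoff: 6.0        # Asp189-Benzamidine frame-level bound cutoff (Angstrom)
msm_lag: 300             # tau = 30 ns at 100 ps/frame
its_lags: [10, 50, 100, 200, 300, 500, 1000]
n_boot: 100              # moving-block bootstrap, block size = lag
n_sets: 7                # gap after the sixth relaxation timescale
bound_cutoff: 6.0        # mean-distance classes: <6 bound
associated_cutoff: 15.0  # 6-15 associated, >15 unbound
kT: 0.5962               # kcal/mol at 300 K
c_sim: 3.7e-3            # simulated ligand concentration (mol/l)
c_ref: 1.0               # standard state
n_pathways: 5
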