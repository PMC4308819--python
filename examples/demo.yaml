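# Synthetic end-to-end demo: three-basin binding trajectories with known
# ground truth, clustered, routed, and post-processed. Deterministic under
# the seed; rerunning reproduces every artifact byte-for-byte.
seed: 7
output_dir: mesopath_demo_out
simulate:
  n_states: 3
  n_atoms: 50
  separation: 3.0      # Angstrom minimum inter-basin reference RMSD
  noise_sigma: 0.5     # Angstrom isotropic thermal scatter
  stay_probability: 0.85
  n_frames: 600
  n_replicas: 2
rmsd:
  tail_fraction: 0.1
clustering:
  threshold: 0.01
  k_max: 10
graph:
  lag: 1
  source: first        # cluster of the first frame (solvated state)
  sinks: last          # cluster of the final frame (bound state)
pathcv:
  lambda_nm2: 100.0
  n_centers: 11
fes:
  n_windows: 15
  kappa: 50.0          # k_BT per S-unit^2
  barrier_kBT: 3.0
  n_samples: 1000
  grid_points: 400
kinetics:
  V_cell_A3: 11086108.0
  n_sites: 3
  n_ligands: 9
  K_D: 9.0e-12
  half_life_s: 832.0   # ~ 20 min residence time scale
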