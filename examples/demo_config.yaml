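# Demo run: two simulated "strains" (membrane-bound vs cytosolic reporter),
# three biological replicates each, one field per replicate.
seed: 1
output_dir: demo_run
band_halfwidth: 0.25
simulate:
  n_replicates: 3
  fields_per_replicate: 1
  base:
    n_cells: 6
    field_shape: [640, 640]
    cell_semiaxis_range: [1.8, 2.4]
  conditions:
    - name: membrane_bound
      membrane_fraction: 0.6
    - name: cytosolic
      membrane_fraction: 0.0
      n_foci: 2
      foci_fraction: 0.15
stats:
  parameter: pm_cytosol_ratio
  channel: GFP
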