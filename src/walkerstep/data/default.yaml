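# Default walker/track/measurement configuration.
#
# Segment counts are nucleotides for single_stranded and base pairs for
# duplex segments. The fuel is attached to the foothold by 18 bp and binds
# the leg by 16 bp; the rear foothold-fuel-leg duplex complex is one
# coaxially stacked rod (18 + 16 bp). Spacers and the inter-leg hinge are
# short flexible linkers.
walker:
  constants:
    ss_contour_nm_per_nt: 0.63
    ss_kuhn_nm: 1.5
    ds_rise_nm_per_bp: 0.34
  capture_radius_nm: 1.0
  bound_arm:
    - {name: t2_spacer, kind: single_stranded, n_units: 2}
    - {name: t2_f2_l2_stack, kind: duplex, n_units: 34}
    - {name: leg_hinge, kind: single_stranded, n_units: 3}
    - {name: l1_free, kind: single_stranded, n_units: 16}
  fuel_arm:
    - {name: t1_spacer, kind: single_stranded, n_units: 2}
    - {name: t1_f1_duplex, kind: duplex, n_units: 18}
    - {name: f1_overhang, kind: single_stranded, n_units: 16}

track:
  kind: flat
  # Tube circumference equals the 60 nm origami width: R = 60 / (2 pi).
  cylinder_radius_nm: 9.5493

kinetics:
  k_FB: 2.3e+5              # fuel-binding rate constant, M^-1 s^-1
  fuel_concentrations: ["1 nM", "10 nM", "100 nM", "1 uM", "10 uM"]
  reference:
    d_ref_nm: 12.0          # step size anchoring relative rates
    k_s_ref: 3.5            # s^-1; short-step stepping rate

fret:
  E_LP: 0.2                 # low-FRET leg-placed population mean
  E_Trap: 0.8               # high-FRET trapped population mean
  sd_LP: 0.1
  sd_Trap: 0.1
  n_bursts: 3000
  n_bootstrap: 200
  # Ground-truth stepping rates (s^-1) for the synthetic experiment.
  true_stepping_rates:
    5: 2.0
    10: 3.5
    12: 3.5
    15: 3.5
    20: 2.5
    25: 1.0
    30: 2.3e-3
    35: 3.5e-5

hairpin:
  enabled: false
  dG_hp_kBT: -2.0           # folding free energy; negative = folded favoured
  sequestered_nt: 10        # fuel-overhang nt unavailable when folded

sampling:
  n_conformations: 100000
  seed: 7
  step_grid_nm: [5, 10, 12, 15, 20, 25, 30, 35]
  grid_spacing_nm: 1.0
  bandwidth_nm: 0.5
  n_bootstrap: 64

output:
  directory: results
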