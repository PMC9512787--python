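# Fixed residue-range selections and validation constants for the augmin
# (HAUS) complex comparative analysis.  Author numbering, inclusive bounds.
selections:
  n_clamp:            # TII N-terminal clamp half
    HAUS2: [[1, 117]]
    HAUS6: [[1, 267]]
    HAUS7: [[1, 270]]
    HAUS8: [[155, 260]]
  c_clamp:            # TII C-terminal clamp half
    HAUS2: [[118, 222]]
    HAUS6: [[268, 398]]
    HAUS7: [[271, 348]]
    HAUS8: [[261, 367]]
  h3_h5_arm:          # superposition anchor on the HAUS3/HAUS5 arm
    HAUS3: [[198, 242], [364, 392]]
    HAUS5: [[172, 275], [419, 446]]
  rigid_n_clamp:      # the N-clamp body docked as one rigid unit
    HAUS2: [[1, 114]]
    HAUS6: [[1, 263]]
    HAUS7: [[1, 261]]
    HAUS8: [[155, 259]]
  hinge_deletions:    # hinge residues removed from the composite model
    HAUS2: [[115, 119]]
    HAUS6: [[264, 275]]
    HAUS7: [[262, 270]]
    HAUS8: [[260, 269]]
  haus6_disordered_removal:
    HAUS6: [[398, 478]]
  splice_arm_tii_contribution:  # segments the arm+TII model contributes
    HAUS3: [[198, 364]]
    HAUS5: [[275, 419]]
  ch_domains:         # HAUS6/HAUS7 calponin-homology domains
    HAUS6: [[1, 146]]
    HAUS7: [[1, 125]]
  ndc80_ch_domain:
    NDC80: [[79, 202]]
  eb3_ch_domain:
    EB3: [[1, 131]]
validation:
  d_max: 30.0            # BS3-compatible Ca-Ca threshold, Angstrom
  score_min: 250.0       # strict aggregate-score filter (score > 250)
  score_norm_factor: 10.0
density:
  resolution: 8.0        # Angstrom, for simulated maps in rigid docking
alignment:
  matrix: BLOSUM62
  gap_open: 10.0
  gap_extend: 1.0
display:
  rmsd_scale: [0.0, 10.0]  # Angstrom colour scale for flexibility profiles
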