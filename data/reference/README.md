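# Reference inputs for published-value reproductions

The reproduction tests in `tests/test_acceptance.py` run against the public
experimental inputs, which this repository does not redistribute. Download
them into this directory:

| file | content |
| --- | --- |
| `exported_crosslinks.tsv` | exported BS3 residue-pair table (columns: protein1, res1, protein2, res2, score) from the public MS deposition |
| `8at2.cif` | deposited TIII tetramer model after flexible fitting (PDB 8AT2) |
| `8at3.cif`, `8at4.cif` | deposited holocomplex models, open and closed conformations (PDB 8AT3 / 8AT4) |
| `haus_ch_predicted.pdb` | HAUS6/HAUS7 CH domains in the predicted hammerhead configuration |
| `haus_ch_tandem.pdb` | the same domains (same chains and numbering) superposed onto the Ndc80/Nuf2 tandem CH arrangement (PDB 3IZ0 on the microtubule lattice) |
| `chain_map_tiii.yaml`, `chain_map_holocomplex.yaml`, `chain_map_ch.yaml` | `chains: {HAUS1: A, ...}` maps from subunit names to the chain ids used in the corresponding files (read the chain assignment from each entry's metadata) |

Without these files the reproduction tests fail with an explanatory message;
the synthetic-ground-truth suite is unaffected.
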