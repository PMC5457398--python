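peptides:
- peptide_id: HT4
  sequence: GLEWLGVIWSGGNTDYNTPFTSR
  average_mass: 2570.8
  transitions:
  - peptide_id: HT4
    channel: light
    precursor_mz: 857.6
    precursor_charge: 3
    product_mz: 908.6
    product_label: y16^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: true
  - peptide_id: HT4
    channel: light
    precursor_mz: 857.6
    precursor_charge: 3
    product_mz: 851.6
    product_label: y15^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: false
  - peptide_id: HT4
    channel: light
    precursor_mz: 857.6
    precursor_charge: 3
    product_mz: 759.0
    product_label: y14^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: false
  - peptide_id: HT4
    channel: heavy
    precursor_mz: 860.9
    precursor_charge: 3
    product_mz: 913.6
    product_label: y16^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: true
  - peptide_id: HT4
    channel: heavy
    precursor_mz: 860.9
    precursor_charge: 3
    product_mz: 857.2
    product_label: y15^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: false
  - peptide_id: HT4
    channel: heavy
    precursor_mz: 860.9
    precursor_charge: 3
    product_mz: 764.0
    product_label: y14^2+
    collision_energy: 16.0
    expected_rt: 8.8
    is_quantifier: false
- peptide_id: LT3
  sequence: ASQSIGTNIHWYQQR
  average_mass: 1788.9
  transitions:
  - peptide_id: LT3
    channel: light
    precursor_mz: 597.2
    precursor_charge: 3
    product_mz: 652.0
    product_label: y10^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: true
  - peptide_id: LT3
    channel: light
    precursor_mz: 597.2
    precursor_charge: 3
    product_mz: 708.6
    product_label: y11^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: false
  - peptide_id: LT3
    channel: light
    precursor_mz: 597.2
    precursor_charge: 3
    product_mz: 752.2
    product_label: y12^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: false
  - peptide_id: LT3
    channel: heavy
    precursor_mz: 600.6
    precursor_charge: 3
    product_mz: 657.0
    product_label: y10^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: true
  - peptide_id: LT3
    channel: heavy
    precursor_mz: 600.6
    precursor_charge: 3
    product_mz: 713.6
    product_label: y11^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: false
  - peptide_id: LT3
    channel: heavy
    precursor_mz: 600.6
    precursor_charge: 3
    product_mz: 757.2
    product_label: y12^2+
    collision_energy: 15.0
    expected_rt: 3.6
    is_quantifier: false
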