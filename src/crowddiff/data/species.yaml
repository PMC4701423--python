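# Polymer and solute property library: molecular weight, hydrodynamic radius,
# and (where reported) the coil overlap concentration measured for the species.
# Gyration radii are not tabulated here; supply them explicitly when computing
# the coil overlap concentration c*.
polymers:
  dextran500:
    name: Dextran 500
    molecular_weight_kda: 500
    hydrodynamic_radius_nm: 15.9
    overlap_concentration_percent: 2.5
  dextran70:
    name: Dextran 70
    molecular_weight_kda: 70
    hydrodynamic_radius_nm: 5.8
    overlap_concentration_percent: 6.9
  ficoll400:
    name: Ficoll
    molecular_weight_kda: 400
    hydrodynamic_radius_nm: 8.0
    overlap_concentration_percent: 9.1
solutes:
  rnase:
    name: RNase
    molecular_weight_kda: 13.7
    hydrodynamic_radius_nm: 1.8
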