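{
  "adult_observations.csv": "bbfc0b2ecae4eae3c312189d1cc70244213ec1bd42521a30ab889730ab5ceb0d",
  "compounds.csv": "00acf7f509399541f2b5c052911a4b6bb4d3d78ebc2708d1c353c917ebdad797",
  "infant_observations.csv": "d4ee3b273f9c32a8543e46bec2a5e72d642e82fd709a1e73cd9633dd760276d0",
  "maturation_models.yaml": "78e08d21f55c4498b26139097ea8127edb16c5c24b18783940bdb784b6141210",
  "sc_thickness_adult.csv": "a79e6b3f5fbc7fb50547699ea55bf6aea047f604252d322df3117e0797b6f7ea"
}
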