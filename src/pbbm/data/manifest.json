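{
 "calibration_media.csv": "75175ea04d52483c026ff134f9033ad14c01570a4aaccedccdf45aeec656a388",
 "compound_model.yaml": "08e5ba50a55262eadda02e2e0c63b52837486e4d3e2b12f3531f40a4a679407c",
 "solubility_screen.csv": "1dc8051a22c050523a9c92ca95a18cd23097e56deb5762392aa09603210f9fa9",
 "table2_media.csv": "3f4a0d4b1bf5f0f47fb55f2be1df92a4cba4f6362c1c96c7a0f3df7a5c5ff935",
 "table4_permeability.csv": "ffc4c73a4a892a05e98d5091e4a4b7fc728dfc2c15dd442b88b241232b21084c",
 "table5_iv.csv": "a28483a4d0a92fd486a922db36cd0cfd385f62de9b249c9e6d32409b786a9828",
 "table6_solubility.csv": "bea97dccdf5f378ab1143787136f54b1dff830da7c163da49eb747fda076c763",
 "table7_logkmw.csv": "cc02f8dfca5a00efe284a0e926ef0dd151289abd393e9eb053a234e650738cc5",
 "table8_pk.csv": "763fcdd26e50a5e7c8d8bb9cb4a5290393063e5d8363e12a4b369c758a0c9f9c"
}
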