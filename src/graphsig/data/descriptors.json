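{
  "version": "1.0",
  "note": "Frozen ordered manifest of the 48 general physicochemical descriptors appended to the 216 signature counts. Names resolve against the descriptor registry in graphsig.chemgraph.",
  "names": [
    "MolWt",
    "HeavyAtomMolWt",
    "ExactMolWt",
    "MolLogP",
    "MolMR",
    "TPSA",
    "LabuteASA",
    "NumHAcceptors",
    "NumHDonors",
    "NumRotatableBonds",
    "NumHeteroatoms",
    "NOCount",
    "NHOHCount",
    "RingCount",
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumSaturatedRings",
    "NumAromaticHeterocycles",
    "NumAromaticCarbocycles",
    "NumAliphaticHeterocycles",
    "NumAliphaticCarbocycles",
    "NumSaturatedHeterocycles",
    "NumSaturatedCarbocycles",
    "HeavyAtomCount",
    "FractionCSP3",
    "FormalCharge",
    "LipinskiViolations",
    "NumSpiroAtoms",
    "NumBridgeheadAtoms",
    "NumAmideBonds",
    "NumValenceElectrons",
    "NumRadicalElectrons",
    "CarbonCount",
    "NitrogenCount",
    "OxygenCount",
    "SulfurCount",
    "PhosphorusCount",
    "HalogenCount",
    "BalabanJ",
    "BertzCT",
    "Chi0",
    "Chi1",
    "Chi0v",
    "Chi1v",
    "HallKierAlpha",
    "Kappa1",
    "Kappa2",
    "Kappa3"
  ]
}
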