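{
  "version": "1.0",
  "note": "Fixed SMARTS panel of substructures repeatedly implicated in anticancer activity screens. Presence frequencies (fraction of molecules with >=1 match) are compared between active and inactive sets. Parent scaffolds are encoded; substitution is tolerated.",
  "patterns": [
    {
      "name": "naphthalene",
      "smarts": "c1ccc2ccccc2c1",
      "provenance": "fused bicyclic aromatic scaffold enriched in actives (CNS, ovarian, NSCLC panels)"
    },
    {
      "name": "lactone",
      "smarts": "[C;R](=O)[O;R]",
      "provenance": "cyclic ester scaffold enriched in actives (leukemia, renal, breast panels)"
    },
    {
      "name": "n_methylaniline",
      "smarts": "c-[NX3;H1]-[CH3]",
      "provenance": "N-methylated aniline motif enriched in actives (prostate, melanoma, colon panels)"
    },
    {
      "name": "quinoline",
      "smarts": "c1ccc2ncccc2c1",
      "provenance": "benzo-fused pyridine scaffold enriched in actives (small-cell lung panel)"
    },
    {
      "name": "benzene",
      "smarts": "c1ccccc1",
      "provenance": "simple aromatic ring; general enrichment in actives"
    },
    {
      "name": "pyridine",
      "smarts": "c1ccncc1",
      "provenance": "azine ring; discriminative feature of actives"
    },
    {
      "name": "amide",
      "smarts": "[CX3](=O)[NX3]",
      "provenance": "amide linkage; discriminative feature of inactives"
    }
  ]
}
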