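{
  "version": "1.0",
  "note": "Atom-level pharmacophore typing rules. Eight classes in frozen order; an atom receives a class tag if it matches ANY of the listed single-atom SMARTS environments. This alphabet is a reconstruction in the pkCSM lineage, not a published table.",
  "classes": [
    {
      "name": "Hydrophobe",
      "smarts": [
        "[c]",
        "[C;!$(C=[O,N,S,P]);!$(C#N)]"
      ]
    },
    {
      "name": "Aromatic",
      "smarts": [
        "[a]"
      ]
    },
    {
      "name": "Donor",
      "smarts": [
        "[#7;!H0;!$([N+]);!$(N~[O])]",
        "[#8;!H0]",
        "[#16;!H0]",
        "[N+;!H0]"
      ]
    },
    {
      "name": "Acceptor",
      "smarts": [
        "[#8;!$([O-]);!$([o])]",
        "[o;X2]",
        "[n;X2;H0;+0]",
        "[N;X1]",
        "[N;X2;H0;+0;!$(N=O)]"
      ]
    },
    {
      "name": "PosIonizable",
      "smarts": [
        "[+;!$([+]~[-])]",
        "[NX3;H2,H1,H0;+0;!$(N~[a]);!$(N-[C,S,P]=[O,N,S]);!$(N=*);!$(N-[O,N])]",
        "[$([NX2]=C-[NX3;+0]);!$(N~[a])]"
      ]
    },
    {
      "name": "NegIonizable",
      "smarts": [
        "[-;!$([-]~[+])]",
        "[$([OX2H1]-[CX3]=O)]",
        "[$([OX2H1]-[SX4](=O)=O)]",
        "[$([OX2H1]-[PX4]=O)]",
        "[$([SX2H1]-[CX3]=O)]"
      ]
    },
    {
      "name": "Halogen",
      "smarts": [
        "[F,Cl,Br,I]"
      ]
    },
    {
      "name": "Sulfur",
      "smarts": [
        "[#16]"
      ]
    }
  ]
}
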