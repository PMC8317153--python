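"""Molecular graphs, pharmacophore atom typing, and general descriptors.

A molecule is modelled as its heavy-atom graph: nodes are non-hydrogen
atoms, edges are covalent bonds with unit weight. On top of the graph two
kinds of chemical annotation are computed:

* a pharmacophore assignment — each atom receives a (possibly empty) set of
  class tags from a fixed 8-class alphabet (Hydrophobe, Aromatic, Donor,
  Acceptor, PosIonizable, NegIonizable, Halogen, Sulfur), defined by a
  versioned SMARTS rule table;
* a block of 48 general physicochemical descriptors (molecular weight,
  logP, TPSA, H-bond counts, ring/topology counts, ...) in a frozen,
  named order.

All chemistry is delegated to RDKit; this module owns the graph contract
and the rule/manifest configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .config import descriptor_config, pharmacophore_config


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be turned into a valid heavy-atom graph."""


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be evaluated for a molecule."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of (the largest covalent fragment of) a molecule.

    Atom indices are 0-based and contiguous; bonds are unordered index
    pairs with unit weight. Hydrogens are suppressed and contribute only
    through per-atom implicit-H counts inside RDKit.
    """

    mol_id: str
    atoms: tuple[tuple[int, str, int, bool, bool], ...]  # (index, element, charge, aromatic, in_ring)
    bonds: tuple[tuple[int, int], ...]
    canonical_smiles: str
    rdmol: Chem.Mol = field(compare=False, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass(frozen=True)
class PharmacophoreAssignment:
    """Per-atom pharmacophore class tags; ``alphabet`` is the frozen class order."""

    mol_id: str
    labels: dict[int, frozenset[str]]
    alphabet: tuple[str, ...]


@dataclass(frozen=True)
class DescriptorBlock:
    """Ordered vector of the 48 general physicochemical descriptors."""

    mol_id: str
    names: tuple[str, ...]
    values: tuple[float, ...]


# ---------------------------------------------------------------------------
# SMILES parsing


def parse_smiles(smiles: str, mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a sanitized heavy-atom molecular graph.

    Multi-fragment inputs (salts, mixtures) are reduced to the largest
    covalent fragment by heavy-atom count; ties are broken by the
    lexicographically smallest canonical SMILES. Stereochemistry is kept in
    the canonical SMILES but plays no role in the graph topology.

    Raises
    ------
    SmilesError
        If the string is empty, fails RDKit sanitization, or no heavy atom
        survives fragment selection.
    """
    if not smiles or not smiles.strip():
        raise SmilesError(f"empty SMILES for mol_id={mol_id!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES {smiles!r} (mol_id={mol_id!r})")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = min(frags, key=lambda f: (-f.GetNumAtoms(), Chem.MolToSmiles(f)))
    if mol.GetNumAtoms() == 0:
        raise SmilesError(f"no heavy atoms left after fragment selection: {smiles!r}")

    # Re-parse from the canonical SMILES so the stored atom order is
    # canonical: descriptor sums then agree bit-for-bit across spellings.
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always re-parses
        raise SmilesError(f"canonical SMILES round-trip failed for {smiles!r}")

    atoms = tuple(
        (a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.IsInRing())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(
        mol_id=mol_id,
        atoms=atoms,
        bonds=bonds,
        canonical_smiles=Chem.MolToSmiles(mol),
        rdmol=mol,
    )


# ---------------------------------------------------------------------------
# Pharmacophore typing


def _compiled_rules() -> list[tuple[str, list[Chem.Mol]]]:
    cfg = pharmacophore_config()
    rules = []
    for cls in cfg["classes"]:
        pats = [Chem.MolFromSmarts(s) for s in cls["smarts"]]
        if any(p is None for p in pats):
            raise ValueError(f"invalid SMARTS in pharmacophore class {cls['name']}")
        rules.append((cls["name"], pats))
    return rules


_RULES_CACHE: list[tuple[str, list[Chem.Mol]]] | None = None


def pharmacophore_alphabet() -> tuple[str, ...]:
    """The frozen ordered list of pharmacophore class names."""
    return tuple(cls["name"] for cls in pharmacophore_config()["classes"])


def assign_pharmacophores(graph: MolecularGraph) -> PharmacophoreAssignment:
    """Tag every atom with the pharmacophore classes whose SMARTS rules it matches.

    Each rule is a single-atom environment pattern; the first atom of every
    substructure match receives the tag. The assignment depends only on the
    molecular graph, so any SMILES spelling of the same molecule yields the
    same multiset of tag sets.
    """
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = _compiled_rules()
    mol = graph.rdmol
    tags: dict[int, set[str]] = {i: set() for i in range(graph.n_atoms)}
    for name, patterns in _RULES_CACHE:
        for pat in patterns:
            for match in mol.GetSubstructMatches(pat, uniquify=False):
                tags[match[0]].add(name)
    return PharmacophoreAssignment(
        mol_id=graph.mol_id,
        labels={i: frozenset(s) for i, s in tags.items()},
        alphabet=pharmacophore_alphabet(),
    )


# ---------------------------------------------------------------------------
# General descriptors


def _lipinski_violations(mol: Chem.Mol) -> int:
    v = 0
    v += Descriptors.MolWt(mol) > 500
    v += Descriptors.MolLogP(mol) > 5
    v += rdMolDescriptors.CalcNumLipinskiHBD(mol) > 5
    v += rdMolDescriptors.CalcNumLipinskiHBA(mol) > 10
    return int(v)


def _element_count(symbols: set[str]):
    def count(mol: Chem.Mol) -> int:
        return sum(a.GetSymbol() in symbols for a in mol.GetAtoms())

    return count


#: name -> callable(Mol) -> float; the JSON manifest fixes which of these
#: are used and in what order.
DESCRIPTOR_REGISTRY = {
    "MolWt": Descriptors.MolWt,
    "HeavyAtomMolWt": Descriptors.HeavyAtomMolWt,
    "ExactMolWt": Descriptors.ExactMolWt,
    "MolLogP": Descriptors.MolLogP,
    "MolMR": Descriptors.MolMR,
    "TPSA": Descriptors.TPSA,
    "LabuteASA": Descriptors.LabuteASA,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NumHDonors": Descriptors.NumHDonors,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "NumHeteroatoms": Descriptors.NumHeteroatoms,
    "NOCount": Descriptors.NOCount,
    "NHOHCount": Descriptors.NHOHCount,
    "RingCount": Descriptors.RingCount,
    "NumAromaticRings": Descriptors.NumAromaticRings,
    "NumAliphaticRings": Descriptors.NumAliphaticRings,
    "NumSaturatedRings": Descriptors.NumSaturatedRings,
    "NumAromaticHeterocycles": Descriptors.NumAromaticHeterocycles,
    "NumAromaticCarbocycles": Descriptors.NumAromaticCarbocycles,
    "NumAliphaticHeterocycles": Descriptors.NumAliphaticHeterocycles,
    "NumAliphaticCarbocycles": Descriptors.NumAliphaticCarbocycles,
    "NumSaturatedHeterocycles": Descriptors.NumSaturatedHeterocycles,
    "NumSaturatedCarbocycles": Descriptors.NumSaturatedCarbocycles,
    "HeavyAtomCount": Descriptors.HeavyAtomCount,
    "FractionCSP3": Descriptors.FractionCSP3,
    "FormalCharge": Chem.GetFormalCharge,
    "LipinskiViolations": _lipinski_violations,
    "NumSpiroAtoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "NumBridgeheadAtoms": rdMolDescriptors.CalcNumBridgeheadAtoms,
    "NumAmideBonds": rdMolDescriptors.CalcNumAmideBonds,
    "NumValenceElectrons": Descriptors.NumValenceElectrons,
    "NumRadicalElectrons": Descriptors.NumRadicalElectrons,
    "CarbonCount": _element_count({"C"}),
    "NitrogenCount": _element_count({"N"}),
    "OxygenCount": _element_count({"O"}),
    "SulfurCount": _element_count({"S"}),
    "PhosphorusCount": _element_count({"P"}),
    "HalogenCount": _element_count({"F", "Cl", "Br", "I"}),
    "BalabanJ": Descriptors.BalabanJ,
    "BertzCT": Descriptors.BertzCT,
    "Chi0": Descriptors.Chi0,
    "Chi1": Descriptors.Chi1,
    "Chi0v": Descriptors.Chi0v,
    "Chi1v": Descriptors.Chi1v,
    "HallKierAlpha": Descriptors.HallKierAlpha,
    "Kappa1": Descriptors.Kappa1,
    "Kappa2": Descriptors.Kappa2,
    "Kappa3": Descriptors.Kappa3,
}


def descriptor_names() -> tuple[str, ...]:
    """The manifest-ordered names of the 48 general descriptors."""
    names = tuple(descriptor_config()["names"])
    missing = [n for n in names if n not in DESCRIPTOR_REGISTRY]
    if missing:
        raise ValueError(f"descriptor manifest names not in registry: {missing}")
    return names


def compute_descriptors(graph: MolecularGraph) -> DescriptorBlock:
    """Evaluate the 48 general descriptors for a molecule, in manifest order."""
    names = descriptor_names()
    values = []
    for name in names:
        try:
            val = float(DESCRIPTOR_REGISTRY[name](graph.rdmol))
        except Exception as exc:  # descriptor-engine failure on exotic input
            raise DescriptorError(f"descriptor {name} failed for {graph.mol_id}: {exc}") from exc
        if val != val or val in (float("inf"), float("-inf")):
            raise DescriptorError(f"descriptor {name} non-finite for {graph.mol_id}")
        values.append(val)
    return DescriptorBlock(mol_id=graph.mol_id, names=names, values=tuple(values))


# ---------------------------------------------------------------------------
# Tabular input


def read_smiles_table(path: str) -> pd.DataFrame:
    """Read a molecule table from a ``.smi`` file or a CSV.

    ``.smi``: one ``SMILES [whitespace] id`` per line (id optional, defaults
    to ``mol<row>``). CSV: must contain ``smiles`` and ``mol_id`` columns.
    Returns a DataFrame with columns ``smiles``, ``mol_id``.
    """
    if str(path).endswith(".smi"):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for k, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"mol{k}"
                rows.append({"smiles": smiles, "mol_id": mol_id})
        return pd.DataFrame(rows, columns=["smiles", "mol_id"])
    df = pd.read_csv(path)
    if not {"smiles", "mol_id"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns smiles,mol_id; found {list(df.columns)}")
    return df[["smiles", "mol_id"]].astype({"mol_id": str})
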