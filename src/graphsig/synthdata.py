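"""Synthetic molecule tables with a planted substructure-activity relationship.

Molecules are assembled by joining 1-4 scaffolds from a small vocabulary
(fused aromatics, azines, lactone, amide, simple carbo/heterocycles and
decorations) through single C-C / C-N bonds at hydrogen-bearing carbons,
so every product is valence-valid. A designated subset of scaffolds is
"active": each planted occurrence raises the activity log-odds by
``fragment_effect`` and the per-cell-line -log10(molar) GI50 by
``gi50_effect``. This gives every downstream module — featurization,
splitting, selection, training, enrichment — a ground truth to recover,
with tunable effect size and noise.

The generator emulates the *structure* of a growth-inhibition screen
(ids, SMILES, binary activity, per-cell-line potencies), not the property
marginals of any real screening library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .datasets import ACTIVE_ABOVE, DEFAULT_DOSE, INACTIVE_BELOW

RDLogger.DisableLog("rdApp.warning")

#: scaffold vocabulary: name -> SMILES
DEFAULT_VOCAB: dict[str, str] = {
    "naphthalene": "c1ccc2ccccc2c1",
    "quinoline": "c1ccc2ncccc2c1",
    "lactone": "O=C1CCCO1",
    "n_methylaniline": "CNc1ccccc1",
    "amide": "CC(N)=O",
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "cyclohexane": "C1CCCCC1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "chlorobenzene": "Clc1ccccc1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "ethyl": "CC",
    "acetic_acid": "CC(=O)O",
}

DEFAULT_ACTIVE_FRAGMENTS = ("naphthalene", "quinoline", "lactone")

DEFAULT_CELL_LINES = ("MCF7", "K-562", "A549", "HCT-116", "SK-MEL-28")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic screen.

    ``fragment_effect`` is the activity log-odds increment per planted
    active-scaffold occurrence; the default (together with
    ``base_active_prob``) makes the planted relationship strong enough to
    be learnable from ~1000 molecules while leaving irreducible label
    noise. ``gi50_base`` is the potency of a molecule with no active
    scaffold, in -log10(molar) (4.5 ~ 30 uM); each active scaffold adds
    ``gi50_effect`` log-units, blurred by Normal(0, noise_sd) per cell
    line.
    """

    n_molecules: int = 1000
    fragment_vocab: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_VOCAB))
    active_fragments: tuple[str, ...] = DEFAULT_ACTIVE_FRAGMENTS
    base_active_prob: float = 0.05
    fragment_effect: float = 6.0
    gi50_base: float = 4.5
    gi50_effect: float = 0.8
    noise_sd: float = 0.3
    min_fragments: int = 1
    max_fragments: int = 4
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    seed: int = 42

    def __post_init__(self):
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be >= 10")
        if not 0 <= self.base_active_prob <= 1:
            raise ValueError("base_active_prob must be a probability")
        unknown = set(self.active_fragments) - set(self.fragment_vocab)
        if unknown:
            raise ValueError(f"active fragments not in vocabulary: {sorted(unknown)}")
        for name, smi in self.fragment_vocab.items():
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"unparsable vocabulary SMILES for {name!r}: {smi!r}")


class AssemblyError(RuntimeError):
    """Fragment joining repeatedly produced invalid molecules."""


def _attachment_atoms(mol: Chem.Mol, symbols=("C",)) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in symbols and a.GetTotalNumHs() >= 1
    ]


def _join(cur: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments by one single bond at random H-bearing atoms."""
    left = _attachment_atoms(cur, symbols=("C",))
    right = _attachment_atoms(frag, symbols=("C", "N"))
    if not left or not right:
        return None
    i = int(rng.choice(left))
    j = int(rng.choice(right))
    combo = Chem.RWMol(Chem.CombineMols(cur, frag))
    combo.AddBond(i, cur.GetNumAtoms() + j, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(names: list[str], vocab: dict[str, str], rng: np.random.Generator,
              max_retries: int = 20) -> str:
    frags = {n: Chem.MolFromSmiles(vocab[n]) for n in set(names)}
    for _ in range(max_retries):
        mol = Chem.Mol(frags[names[0]])
        ok = True
        for name in names[1:]:
            joined = _join(mol, frags[name], rng)
            if joined is None:
                ok = False
                break
            mol = joined
        if ok:
            smi = Chem.MolToSmiles(mol)
            if Chem.MolFromSmiles(smi) is not None:
                return smi
    raise AssemblyError(f"could not assemble a valid molecule from {names}")


def generate_molecules(config: GeneratorConfig) -> pd.DataFrame:
    """Sample the molecule table: mol_id, smiles, planted fragment provenance.

    Each molecule is built from ``min_fragments``..``max_fragments``
    scaffolds drawn uniformly with replacement from the vocabulary.
    Deterministic per seed; every emitted SMILES re-parses.
    """
    rng = np.random.default_rng(config.seed)
    vocab_names = sorted(config.fragment_vocab)
    active = set(config.active_fragments)
    rows = []
    for k in range(config.n_molecules):
        n_frag = int(rng.integers(config.min_fragments, config.max_fragments + 1))
        names = [vocab_names[int(i)] for i in rng.integers(0, len(vocab_names), n_frag)]
        smiles = _assemble(names, config.fragment_vocab, rng)
        rows.append(
            {
                "mol_id": f"synth{k:05d}",
                "smiles": smiles,
                "fragments": ";".join(names),
                "n_active_fragments": sum(n in active for n in names),
            }
        )
    return pd.DataFrame(rows)


def generate_labels(
    table: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw activity labels and per-cell-line GI50 values for a molecule table.

    P(active) = logistic(logit(base_active_prob) + fragment_effect * c)
    where c is the planted active-scaffold count;
    GI50 (as -log10 molar) = gi50_base + gi50_effect * c + Normal(0, noise_sd),
    drawn independently per cell line.

    Returns ``(labels, gi50)``: labels has columns mol_id, active (0/1),
    p_active, n_active_fragments; gi50 is long-format (mol_id, cell_line,
    neglog_gi50).
    """
    if "n_active_fragments" not in table.columns:
        raise ValueError("table must come from generate_molecules")
    rng = np.random.default_rng([config.seed, 7919])
    c = table["n_active_fragments"].to_numpy(dtype=float)
    base = np.clip(config.base_active_prob, 1e-12, 1 - 1e-12)
    logit = np.log(base / (1 - base)) + config.fragment_effect * c
    p = 1.0 / (1.0 + np.exp(-logit))
    active = (rng.random(len(table)) < p).astype(int)
    labels = pd.DataFrame(
        {
            "mol_id": table["mol_id"],
            "active": active,
            "p_active": p,
            "n_active_fragments": table["n_active_fragments"],
        }
    )
    gi_rows = []
    for line in config.cell_lines:
        vals = config.gi50_base + config.gi50_effect * c + rng.normal(0, config.noise_sd, len(table))
        gi_rows.append(
            pd.DataFrame(
                {"mol_id": table["mol_id"], "cell_line": line, "neglog_gi50": vals}
            )
        )
    return labels, pd.concat(gi_rows, ignore_index=True)


def activity_records(labels: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Emit assay-style growth-inhibition rows consistent with the labels.

    Actives get a dose-response mean inhibition above the 50% rule,
    inactives a one-dose mean below the 5% rule, both at the standard
    1e-5 mol dose, so the labelling rules recover the planted labels
    exactly.
    """
    rng = np.random.default_rng([config.seed, 104729])
    rows = []
    for rec in labels.itertuples(index=False):
        if rec.active:
            mean = ACTIVE_ABOVE + 1.0 + abs(rng.normal(20, 8))
            assay = "dose_response"
        else:
            mean = min(INACTIVE_BELOW - 1.0, rng.normal(0, 2))
            assay = "one_dose"
        rows.append(
            {
                "mol_id": rec.mol_id,
                "assay": assay,
                "mean_inhibition": float(mean),
                "dose": DEFAULT_DOSE,
            }
        )
    return pd.DataFrame(rows)
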