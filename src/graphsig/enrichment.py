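"""Property and substructure enrichment between active and inactive sets.

Two complementary views of what separates actives from inactives:

* distribution shifts in physicochemical properties, quantified by the
  two-sample Kolmogorov-Smirnov statistic on the active vs inactive
  property values;
* presence frequencies of a fixed panel of SMARTS substructures (fused
  aromatics, lactone, N-methylaniline, quinoline, benzene, pyridine,
  amide), reported as the percentage of molecules in each set with at
  least one match. Frequent-subgraph *mining* is out of scope — the panel
  is fixed, versioned configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from scipy import stats

from .config import fragment_config


@dataclass(frozen=True)
class FragmentPattern:
    """A named SMARTS substructure with a provenance note."""

    name: str
    smarts: str
    provenance: str = ""

    def compile(self) -> Chem.Mol:
        pat = Chem.MolFromSmarts(self.smarts)
        if pat is None:
            raise ValueError(f"invalid SMARTS for pattern {self.name!r}: {self.smarts!r}")
        return pat


def default_patterns() -> list[FragmentPattern]:
    """The frozen substructure panel shipped with the package."""
    cfg = fragment_config()
    pats = [FragmentPattern(p["name"], p["smarts"], p.get("provenance", "")) for p in cfg["patterns"]]
    names = [p.name for p in pats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pattern names in fragment panel")
    return pats


def _presence_fraction(smiles_set, pattern: Chem.Mol) -> tuple[int, int]:
    """(#molecules with >=1 match, #parsable molecules)."""
    hits = 0
    total = 0
    for smi in smiles_set:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            warnings.warn(f"unparsable SMILES excluded from enrichment: {smi!r}")
            continue
        total += 1
        hits += mol.HasSubstructMatch(pattern)
    return hits, total


def fragment_frequencies(
    actives: list[str],
    inactives: list[str],
    patterns: list[FragmentPattern] | None = None,
) -> pd.DataFrame:
    """Per-pattern presence frequencies (percent) in active vs inactive molecules.

    A molecule counts once per pattern no matter how many times the pattern
    matches. Unparsable SMILES are excluded from the denominator with a
    warning. Returns a DataFrame with columns ``pattern``, ``freq_active``,
    ``freq_inactive``, ``n_active``, ``n_inactive``, sorted by descending
    active/inactive frequency ratio.
    """
    if not actives or not inactives:
        raise ValueError("both active and inactive sets must be non-empty")
    patterns = patterns if patterns is not None else default_patterns()
    rows = []
    for pat in patterns:
        compiled = pat.compile()
        hits_a, n_a = _presence_fraction(actives, compiled)
        hits_i, n_i = _presence_fraction(inactives, compiled)
        if n_a == 0 or n_i == 0:
            raise ValueError("no parsable molecules in one of the sets")
        rows.append(
            {
                "pattern": pat.name,
                "freq_active": 100.0 * hits_a / n_a,
                "freq_inactive": 100.0 * hits_i / n_i,
                "n_active": n_a,
                "n_inactive": n_i,
            }
        )
    df = pd.DataFrame(rows)
    ratio = df["freq_active"] / df["freq_inactive"].where(df["freq_inactive"] > 0, 0.5 / df["n_inactive"] * 100)
    return df.assign(_r=ratio).sort_values("_r", ascending=False).drop(columns="_r").reset_index(drop=True)


def ks_property_comparison(values_active, values_inactive) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of a property distribution.

    Returns (D, p): D is the supremum distance between the two empirical
    CDFs, p the two-sided asymptotic p-value. Identical constant samples
    give D = 0, p = 1.
    """
    if len(values_active) < 5 or len(values_inactive) < 5:
        raise ValueError("need at least 5 values per sample")
    res = stats.ks_2samp(values_active, values_inactive, method="asymp")
    return float(res.statistic), float(res.pvalue)
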