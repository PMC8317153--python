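"""Activity labelling, GI50 curation, and non-redundant dataset splitting.

Labelling follows the two-rule growth-inhibition scheme used for the
NCI-60 screen: a molecule is *inactive* when its mean growth inhibition on
one-dose data is below 5% at 1e-5 mol, and *active* when its mean growth
inhibition on dose-response data exceeds 50% at the same dose. Molecules
that satisfy neither rule stay unlabelled (and are excluded from
classification training); a molecule satisfying both is a conflict.

Train/blind splitting is made non-redundant by clustering molecules on
Morgan fingerprints (radius 2, 2048 bits) with Butina leader clustering at
Tanimoto 0.6, then assigning whole clusters to one side, so no pair of
similar molecules straddles the partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

log = logging.getLogger(__name__)

DEFAULT_DOSE = 1e-5  # mol
INACTIVE_BELOW = 5.0  # % growth inhibition, one-dose assay
ACTIVE_ABOVE = 50.0  # % growth inhibition, dose-response assay

FP_RADIUS = 2
FP_NBITS = 2048


class Assay(str, Enum):
    one_dose = "one_dose"
    dose_response = "dose_response"


class Label(str, Enum):
    active = "active"
    inactive = "inactive"
    unlabeled = "unlabeled"


@dataclass(frozen=True)
class ActivityRecord:
    """One molecule's growth-inhibition evidence at a given dose (mol)."""

    mol_id: str
    assay: Assay
    mean_inhibition: float  # percent; may be negative or >100
    dose: float

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")


@dataclass(frozen=True)
class GI50Record:
    """A -log10(molar) GI50 observation for one molecule on one cell line."""

    mol_id: str
    cell_line: str
    neglog_gi50: float


class LabelConflictError(ValueError):
    """Both the active and the inactive rule fired for the same molecule."""

    def __init__(self, mol_ids):
        self.mol_ids = list(mol_ids)
        super().__init__(f"conflicting activity labels for: {self.mol_ids}")


def label_activity(
    records: list[ActivityRecord],
    dose_target: float = DEFAULT_DOSE,
    *,
    on_conflict: str = "warn",
) -> dict[str, Label]:
    """Apply the two-threshold labelling rules to grouped assay records.

    Per molecule, the mean inhibition is averaged within each assay type
    over records at ``dose_target``. The inactive rule uses strict < 5% on
    one-dose data; the active rule strict > 50% on dose-response data.

    ``on_conflict``: ``"warn"`` excludes conflicting molecules with a
    warning; ``"raise"`` raises :class:`LabelConflictError`.
    """
    by_mol: dict[str, dict[Assay, list[float]]] = {}
    for rec in records:
        if not np.isclose(rec.dose, dose_target, rtol=1e-6):
            continue
        by_mol.setdefault(rec.mol_id, {}).setdefault(Assay(rec.assay), []).append(
            rec.mean_inhibition
        )

    labels: dict[str, Label] = {}
    conflicts = []
    for mol_id, groups in by_mol.items():
        inactive = (
            Assay.one_dose in groups
            and float(np.mean(groups[Assay.one_dose])) < INACTIVE_BELOW
        )
        active = (
            Assay.dose_response in groups
            and float(np.mean(groups[Assay.dose_response])) > ACTIVE_ABOVE
        )
        if active and inactive:
            conflicts.append(mol_id)
            continue
        labels[mol_id] = Label.active if active else Label.inactive if inactive else Label.unlabeled
    if conflicts:
        if on_conflict == "raise":
            raise LabelConflictError(conflicts)
        warnings.warn(f"excluded molecules with conflicting labels: {sorted(conflicts)}")
    return labels


def curate_gi50(rows: pd.DataFrame, known_cell_lines: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Merge replicate GI50 observations and split them into per-cell-line tables.

    Replicate (mol_id, cell_line) rows are combined by arithmetic mean on
    the -log10(molar) scale. When ``known_cell_lines`` is given, rows with
    an unrecognised cell-line name are routed to a ``"_misc"`` table with a
    warning instead of being dropped.
    """
    required = {"mol_id", "cell_line", "neglog_gi50"}
    if not required.issubset(rows.columns):
        raise ValueError(f"GI50 table needs columns {sorted(required)}")
    if not np.isfinite(rows["neglog_gi50"]).all():
        raise ValueError("non-finite neglog_gi50 values")

    merged = (
        rows.groupby(["cell_line", "mol_id"], as_index=False, sort=True)["neglog_gi50"]
        .mean()
    )
    tables: dict[str, pd.DataFrame] = {}
    for cell_line, sub in merged.groupby("cell_line", sort=True):
        key = str(cell_line)
        if known_cell_lines is not None and key not in known_cell_lines:
            warnings.warn(f"unknown cell line {key!r}; routed to _misc")
            if "_misc" in tables:
                tables["_misc"] = pd.concat([tables["_misc"], sub], ignore_index=True)
            else:
                tables["_misc"] = sub.reset_index(drop=True)
            continue
        tables[key] = sub.reset_index(drop=True)
    return tables


# ---------------------------------------------------------------------------
# Non-redundant splitting


@dataclass(frozen=True)
class DatasetSplit:
    """Cluster-respecting train/blind partition with its provenance."""

    threshold: float
    fraction_train: float
    clusters: dict[str, int]  # mol_id -> cluster id
    partition: dict[int, str]  # cluster id -> "train" | "blind"
    seed: int = field(default=0)

    @property
    def train_ids(self) -> list[str]:
        return [m for m, c in self.clusters.items() if self.partition[c] == "train"]

    @property
    def blind_ids(self) -> list[str]:
        return [m for m, c in self.clusters.items() if self.partition[c] == "blind"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_id": list(self.clusters),
                "cluster_id": [self.clusters[m] for m in self.clusters],
                "partition": [self.partition[self.clusters[m]] for m in self.clusters],
            }
        )


def morgan_fingerprints(smiles_list: list[str]) -> list:
    """Morgan/circular bit fingerprints (radius 2, 2048 bits) for valid SMILES."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES in split input: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def butina_clusters(fps: list, mol_ids: list[str], threshold: float = 0.6) -> dict[str, int]:
    """Leader (sphere-exclusion) clustering on Tanimoto similarity.

    Molecules within ``threshold`` similarity of a centroid join its
    cluster. Centroids are chosen by descending neighbour count with ties
    broken by lexicographic mol_id, which makes the clustering fully
    deterministic. Cluster ids are assigned in centroid-selection order.
    """
    n = len(fps)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        for j, s in enumerate(sims):
            if s >= threshold:
                neighbors[i].add(j)
                neighbors[j].add(i)

    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), mol_ids[i]))
    assigned: dict[int, int] = {}
    cluster_id = 0
    for centroid in order:
        if centroid in assigned:
            continue
        assigned[centroid] = cluster_id
        for nb in neighbors[centroid]:
            if nb not in assigned:
                assigned[nb] = cluster_id
        cluster_id += 1
    return {mol_ids[i]: assigned[i] for i in range(n)}


def cluster_and_split(
    table: pd.DataFrame,
    threshold: float = 0.6,
    fraction_train: float = 0.8,
    seed: int = 42,
) -> DatasetSplit:
    """Cluster molecules and assign whole clusters to train or blind.

    Clusters are taken largest-first (equal sizes shuffled by ``seed``) and
    each is placed on the side currently furthest below its quota, which
    keeps the realised train fraction near ``fraction_train`` without ever
    splitting a cluster. A degenerate input (every molecule in one cluster)
    puts everything in train and warns.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 molecules to split")
    mol_ids = [str(m) for m in table["mol_id"]]
    if len(set(mol_ids)) != len(mol_ids):
        raise ValueError("duplicate mol_id values in split input")
    fps = morgan_fingerprints(list(table["smiles"]))
    clusters = butina_clusters(fps, mol_ids, threshold)

    members: dict[int, list[str]] = {}
    for m, c in clusters.items():
        members.setdefault(c, []).append(m)

    rng = np.random.default_rng(seed)
    cluster_order = list(members)
    rng.shuffle(cluster_order)
    cluster_order.sort(key=lambda c: -len(members[c]))

    n_total = len(mol_ids)
    quota = {"train": fraction_train * n_total, "blind": (1 - fraction_train) * n_total}
    filled = {"train": 0, "blind": 0}
    partition: dict[int, str] = {}
    for c in cluster_order:
        deficit = {s: quota[s] - filled[s] for s in ("train", "blind")}
        side = "train" if deficit["train"] >= deficit["blind"] else "blind"
        partition[c] = side
        filled[side] += len(members[c])

    if filled["blind"] == 0:
        warnings.warn(
            "all molecules fell in clusters assigned to train; blind set is empty"
        )
    realized = filled["train"] / n_total
    log.info("split: %d clusters, realized train fraction %.3f", len(members), realized)
    return DatasetSplit(
        threshold=threshold,
        fraction_train=fraction_train,
        clusters=clusters,
        partition=partition,
        seed=seed,
    )
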