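"""Graph-based signature featurization.

The signature of a molecule is the cumulative distribution of
pharmacophore-class pair distances in its heavy-atom graph: entry
(A, B, k) counts the unordered atom pairs {i, j} where one atom carries
class A, the other class B, and the shortest-path distance between them
(number of edges, all edges unit weight) is at most k. With 8 classes and
distance cutoffs k = 1..6 this gives 36 x 6 = 216 counts; appending the 48
general descriptors yields the fixed 264-dimensional feature vector.

Shortest paths on a unit-weight graph are computed by breadth-first search
from every node, which is exactly what Johnson's algorithm reduces to when
all edge weights are equal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .chemgraph import (
    DescriptorBlock,
    MolecularGraph,
    PharmacophoreAssignment,
    SmilesError,
    assign_pharmacophores,
    compute_descriptors,
    descriptor_names,
    parse_smiles,
    pharmacophore_alphabet,
)

#: distance cutoffs, in graph steps, of the cumulative signature
DISTANCE_CUTOFFS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

_UNREACHABLE = -1


class DisconnectedGraphError(ValueError):
    """Raised when a distance matrix is requested for a multi-fragment graph."""


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path (edge-count) distances of a single-fragment graph."""

    mol_id: str
    d: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class SignatureVector:
    """The frozen-order 264-feature vector: 216 signature counts + 48 descriptors."""

    mol_id: str
    feature_names: tuple[str, ...]
    values: np.ndarray


def class_pairs(alphabet: tuple[str, ...] | None = None) -> tuple[tuple[str, str], ...]:
    """Unordered class pairs (incl. same-class pairs) in frozen alphabet order."""
    if alphabet is None:
        alphabet = pharmacophore_alphabet()
    return tuple(combinations_with_replacement(alphabet, 2))


def signature_feature_names(alphabet: tuple[str, ...] | None = None) -> tuple[str, ...]:
    return tuple(
        f"Sig:{a}:{b}:d{k}" for (a, b) in class_pairs(alphabet) for k in DISTANCE_CUTOFFS
    )


def feature_names() -> tuple[str, ...]:
    """All 264 feature names: signature block then descriptor block."""
    return signature_feature_names() + descriptor_names()


def shortest_path_matrix(graph: MolecularGraph) -> DistanceMatrix:
    """Exact all-pairs edge-count distances by BFS from every atom.

    Raises :class:`DisconnectedGraphError` if any atom pair is unreachable —
    upstream parsing must already have reduced the molecule to its largest
    covalent fragment.
    """
    n = graph.n_atoms
    adj = graph.adjacency()
    d = np.full((n, n), _UNREACHABLE, dtype=np.int64)
    for src in range(n):
        d[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if d[src, v] == _UNREACHABLE:
                    d[src, v] = d[src, u] + 1
                    queue.append(v)
    if n and (d == _UNREACHABLE).any():
        raise DisconnectedGraphError(
            f"molecule {graph.mol_id!r} has >1 connected component"
        )
    return DistanceMatrix(mol_id=graph.mol_id, d=d)


def signature_counts(
    dist: DistanceMatrix, labels: PharmacophoreAssignment
) -> np.ndarray:
    """Cumulative pharmacophore-pair counts: the 216-entry signature block.

    For each unordered atom pair {i, j} (i != j) and each unordered class
    pair {A, B} such that one atom carries A and the other carries B, the
    pair contributes 1 to every cutoff k >= d[i, j]. A pair of atoms that
    both carry both classes still counts once per class pair.
    """
    n = dist.n_atoms
    if set(labels.labels) != set(range(n)):
        raise ValueError("pharmacophore labels do not cover the distance matrix atoms")
    alphabet = labels.alphabet
    # bool membership matrix: classes x atoms
    member = np.zeros((len(alphabet), n), dtype=bool)
    for idx in range(n):
        for cls in labels.labels[idx]:
            member[alphabet.index(cls), idx] = True

    pairs = class_pairs(alphabet)
    out = np.zeros(len(pairs) * len(DISTANCE_CUTOFFS), dtype=np.int64)
    if n < 2:
        return out
    triu = np.triu(np.ones((n, n), dtype=bool), k=1)
    for p, (a, b) in enumerate(pairs):
        xa = member[alphabet.index(a)]
        xb = member[alphabet.index(b)]
        # unordered atom pair condition: A on one end, B on the other
        cond = (np.outer(xa, xb) | np.outer(xb, xa)) & triu
        dvals = dist.d[cond]
        for q, k in enumerate(DISTANCE_CUTOFFS):
            out[p * len(DISTANCE_CUTOFFS) + q] = int((dvals <= k).sum())
    return out


def featurize(
    graph: MolecularGraph,
    labels: PharmacophoreAssignment | None = None,
    descriptors: DescriptorBlock | None = None,
) -> SignatureVector:
    """Assemble the full 264-feature vector for one molecule.

    ``labels`` and ``descriptors`` are computed on demand when not supplied;
    when supplied they must share the graph's ``mol_id``.
    """
    if labels is None:
        labels = assign_pharmacophores(graph)
    if descriptors is None:
        descriptors = compute_descriptors(graph)
    if not (graph.mol_id == labels.mol_id == descriptors.mol_id):
        raise ValueError("graph, labels and descriptors disagree on mol_id")

    sig = signature_counts(shortest_path_matrix(graph), labels).astype(float)
    names = signature_feature_names(labels.alphabet) + descriptors.names
    values = np.concatenate([sig, np.asarray(descriptors.values, dtype=float)])
    if len(names) != len(values) or len(values) != 264:
        raise AssertionError(
            f"feature vector length {len(values)} != 264 for {graph.mol_id!r}"
        )
    return SignatureVector(mol_id=graph.mol_id, feature_names=tuple(names), values=values)


def featurize_batch(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Featurize a ``smiles``/``mol_id`` table.

    Returns ``(matrix, failures)``: the feature matrix has one row per
    successfully featurized molecule (input order preserved, indexed by
    mol_id); ``failures`` lists molecules that could not be processed with
    the reason. Duplicate mol_ids are rejected outright.
    """
    if not {"smiles", "mol_id"}.issubset(table.columns):
        raise ValueError("table must have smiles and mol_id columns")
    dupes = table["mol_id"][table["mol_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate mol_id values: {sorted(map(str, dupes))}")

    rows, index, failures = [], [], []
    for rec in table.itertuples(index=False):
        try:
            vec = featurize(parse_smiles(rec.smiles, str(rec.mol_id)))
        except (SmilesError, ValueError) as exc:
            failures.append({"mol_id": str(rec.mol_id), "smiles": rec.smiles, "error": str(exc)})
            continue
        rows.append(vec.values)
        index.append(vec.mol_id)

    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, 264)),
        index=pd.Index(index, name="mol_id"),
        columns=list(feature_names()),
    )
    return matrix, pd.DataFrame(failures, columns=["mol_id", "smiles", "error"])
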