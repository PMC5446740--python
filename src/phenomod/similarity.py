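"""Module similarity, phenotypic similarity, and the global objective.

The optimizer drives the pairwise Jaccard similarity of disease modules
toward a fixed gold-standard phenotypic similarity matrix by minimizing

    E(M) = sum over disease pairs i < j of (PhenSim[i,j] - Jaccard(M_i, M_j))^2

Because one annealing move changes a single disease's module, the change in
E touches only the D-1 pairs involving that disease; ``delta_objective``
exploits this for an O(D * |module|) step cost instead of O(D^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "jaccard",
    "cosine_similarity",
    "count_disease_pairs",
    "objective",
    "delta_objective",
    "module_similarity_matrix",
    "PhenotypeSimilarityMatrix",
]


def jaccard(a: set[str], b: set[str]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; 0 when both sets are empty.

    The empty/empty convention keeps the function total; in a normal run it
    is unreachable because every module contains a non-empty seed.
    """
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity between two non-negative symptom-count vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def count_disease_pairs(d: int) -> int:
    """Number of unordered disease pairs summed by the objective: d(d-1)/2."""
    if d < 1:
        raise ValueError("need at least one disease")
    return d * (d - 1) // 2


@dataclass(frozen=True)
class PhenotypeSimilarityMatrix:
    """Gold-standard pairwise disease phenotypic similarity.

    Attributes
    ----------
    disease_ids
        Ordered disease identifiers indexing ``values``.
    values
        Symmetric D×D matrix with entries in [0, 1].
    symptom_vectors
        Optional per-disease non-negative symptom vectors from which
        ``values`` were derived by cosine similarity.
    """

    disease_ids: tuple[str, ...]
    values: np.ndarray
    symptom_vectors: Mapping[str, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        ids = tuple(self.disease_ids)
        object.__setattr__(self, "disease_ids", ids)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(ids), len(ids)):
            raise ValueError(
                f"similarity matrix shape {vals.shape} does not match "
                f"{len(ids)} diseases"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate disease identifiers")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "_index", {d: i for i, d in enumerate(ids)})

    @classmethod
    def from_symptom_vectors(
        cls, vectors: Mapping[str, Sequence[float]]
    ) -> "PhenotypeSimilarityMatrix":
        """Build the matrix as pairwise cosine similarity of symptom vectors."""
        ids = tuple(vectors)
        arrs = {d: np.asarray(vectors[d], dtype=float) for d in ids}
        n = len(ids)
        vals = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = cosine_similarity(arrs[ids[i]], arrs[ids[j]])
        return cls(ids, vals, symptom_vectors=arrs)

    def index(self, disease_id: str) -> int:
        return self._index[disease_id]

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def restrict(self, disease_ids: Iterable[str]) -> "PhenotypeSimilarityMatrix":
        """Sub-matrix over ``disease_ids`` (kept in the given order)."""
        ids = tuple(disease_ids)
        idx = [self._index[d] for d in ids]
        return PhenotypeSimilarityMatrix(ids, self.values[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.disease_ids)


def _check_alignment(
    modules: Mapping[str, set[str]], phen: PhenotypeSimilarityMatrix
) -> None:
    if set(modules) != set(phen.disease_ids):
        only_m = set(modules) - set(phen.disease_ids)
        only_p = set(phen.disease_ids) - set(modules)
        raise ValueError(
            "modules and phenotypic similarity cover different diseases "
            f"(modules-only: {sorted(only_m)[:3]}, matrix-only: {sorted(only_p)[:3]})"
        )


def module_similarity_matrix(
    modules: Mapping[str, set[str]], disease_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Pairwise Jaccard similarity matrix of the given modules."""
    ids = list(disease_ids) if disease_ids is not None else list(modules)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        mi = modules[ids[i]]
        out[i, i] = 1.0 if mi else 0.0
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jaccard(mi, modules[ids[j]])
    return out


def objective(
    modules: Mapping[str, set[str]], phen: PhenotypeSimilarityMatrix
) -> float:
    """Sum of squared phenotypic-vs-module similarity gaps over pairs i < j."""
    _check_alignment(modules, phen)
    ids = phen.disease_ids
    total = 0.0
    for i in range(len(ids)):
        mi = modules[ids[i]]
        for j in range(i + 1, len(ids)):
            gap = phen.values[i, j] - jaccard(mi, modules[ids[j]])
            total += gap * gap
    return total


def delta_objective(
    k: str,
    new_module: set[str],
    modules: Mapping[str, set[str]],
    phen: PhenotypeSimilarityMatrix,
) -> float:
    """Objective change if disease ``k`` switched to ``new_module``.

    Touches only the D-1 pairs involving ``k``; equal to the full-recompute
    difference up to floating-point roundoff.
    """
    _check_alignment(modules, phen)
    ki = phen.index(k)
    old_module = modules[k]
    delta = 0.0
    for j, d in enumerate(phen.disease_ids):
        if d == k:
            continue
        s = phen.values[ki, j]
        other = modules[d]
        gap_new = s - jaccard(new_module, other)
        gap_old = s - jaccard(old_module, other)
        delta += gap_new * gap_new - gap_old * gap_old
    return delta
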