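"""Readers and writers for every on-disk format the pipeline touches.

All files are plain tab-separated text; lines starting with ``#`` are
comments.  Identifiers are opaque case-sensitive strings — no gene-symbol
mapping is attempted.

Formats
-------
network
    two columns: ``protein_a<TAB>protein_b`` (undirected edge list)
associations
    two columns: ``disease_id<TAB>protein_id``
phenotypic similarity
    either long-form triples ``disease_a<TAB>disease_b<TAB>similarity`` or a
    symptom-count matrix (header: symptom names; rows: disease id followed
    by counts), from which cosine similarity is computed
pathways
    standard GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...``
modules
    three columns: ``disease_id<TAB>protein_id<TAB>role`` with role in
    ``{seed, predicted}``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annealer import ModuleState
from .network import ProteinNetwork, largest_connected_component
from .similarity import PhenotypeSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunBundle",
    "load_dataset",
    "read_network",
    "read_associations",
    "write_associations",
    "read_phenotype_similarity",
    "write_similarity_triples",
    "read_gmt",
    "write_gmt",
    "read_modules",
    "write_modules",
    "write_trace",
]


class FormatError(ValueError):
    """Malformed input file; the message names the file and line number."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_network(path: str | Path) -> ProteinNetwork:
    """Load an undirected edge list; self-loops dropped, duplicates merged."""
    edges: list[tuple[str, str]] = []
    self_loops = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise FormatError(f"{path}:{lineno}: empty protein identifier")
        if a == b:
            self_loops += 1
        edges.append((a, b))
    net = ProteinNetwork(edges)
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    return net


def read_associations(path: str | Path) -> dict[str, set[str]]:
    """Load a disease→protein association table (two-column TSV)."""
    table: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        disease, protein = fields[0].strip(), fields[1].strip()
        if not disease or not protein:
            raise FormatError(f"{path}:{lineno}: empty identifier")
        table.setdefault(disease, set()).add(protein)
    if not table:
        raise FormatError(f"{path}: no associations found")
    return table


def write_associations(table: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_id\tprotein_id\n")
        for disease in sorted(table):
            for protein in sorted(table[disease]):
                fh.write(f"{disease}\t{protein}\n")


def read_phenotype_similarity(
    path: str | Path, kind: str = "auto"
) -> PhenotypeSimilarityMatrix:
    """Load pairwise disease phenotypic similarity.

    ``kind='triples'`` reads long-form ``(disease_a, disease_b, similarity)``
    rows; missing reverse pairs are symmetrized, conflicting duplicates
    (beyond 1e-9) are an error, and unlisted pairs default to similarity 0.
    ``kind='symptoms'`` reads a disease × symptom count matrix and computes
    pairwise cosine similarity.  ``'auto'`` treats three-column numeric rows
    as triples and anything else as a symptom matrix.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty similarity file")
    if kind == "auto":
        first = rows[0][1]
        is_triple = len(first) == 3 and _is_float(first[2])
        kind = "triples" if is_triple else "symptoms"
    if kind == "triples":
        return _similarity_from_triples(path, rows)
    if kind == "symptoms":
        return _similarity_from_symptoms(path, rows)
    raise ValueError(f"unknown similarity format {kind!r}")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _similarity_from_triples(
    path: str | Path, rows: list[tuple[int, list[str]]]
) -> PhenotypeSimilarityMatrix:
    entries: dict[tuple[str, str], float] = {}
    diseases: set[str] = set()
    for lineno, fields in rows:
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected three columns")
        a, b, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if not _is_float(raw):
            raise FormatError(f"{path}:{lineno}: similarity {raw!r} is not a number")
        s = float(raw)
        if not (0.0 <= s <= 1.0):
            raise FormatError(f"{path}:{lineno}: similarity {s} outside [0, 1]")
        diseases.update((a, b))
        key = (a, b)
        rev = (b, a)
        if rev in entries and abs(entries[rev] - s) > 1e-9:
            raise FormatError(
                f"{path}:{lineno}: asymmetric similarity for ({a}, {b}): "
                f"{s} vs {entries[rev]}"
            )
        if key in entries and abs(entries[key] - s) > 1e-9:
            raise FormatError(f"{path}:{lineno}: conflicting duplicate for ({a}, {b})")
        entries[key] = s
    ids = tuple(sorted(diseases))
    index = {d: i for i, d in enumerate(ids)}
    values = np.eye(len(ids))
    for (a, b), s in entries.items():
        if a == b:
            continue
        values[index[a], index[b]] = s
        values[index[b], index[a]] = s
    return PhenotypeSimilarityMatrix(ids, values)


def _similarity_from_symptoms(
    path: str | Path, rows: list[tuple[int, list[str]]]
) -> PhenotypeSimilarityMatrix:
    header_lineno, header = rows[0]
    n_symptoms = len(header) - 1
    if n_symptoms < 1:
        raise FormatError(f"{path}:{header_lineno}: symptom matrix needs columns")
    vectors: dict[str, np.ndarray] = {}
    for lineno, fields in rows[1:]:
        if len(fields) != n_symptoms + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {n_symptoms + 1} columns, got {len(fields)}"
            )
        disease = fields[0].strip()
        try:
            vec = np.array([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric symptom count") from exc
        if np.any(vec < 0):
            raise FormatError(f"{path}:{lineno}: negative symptom count")
        if not np.any(vec):
            raise FormatError(f"{path}:{lineno}: all-zero symptom vector")
        vectors[disease] = vec
    if not vectors:
        raise FormatError(f"{path}: no disease rows in symptom matrix")
    ordered = {d: vectors[d] for d in sorted(vectors)}
    return PhenotypeSimilarityMatrix.from_symptom_vectors(ordered)


def write_similarity_triples(
    phen: PhenotypeSimilarityMatrix, path: str | Path
) -> None:
    """Write the upper triangle as long-form triples (deterministic order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_a\tdisease_b\tsimilarity\n")
        ids = phen.disease_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                fh.write(f"{ids[i]}\t{ids[j]}\t{phen.values[i, j]:.10g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Load a GMT pathway collection (name, description, member genes)."""
    pathways: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT rows need name, description and >=1 gene"
            )
        name = fields[0].strip()
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if not name or not genes:
            raise FormatError(f"{path}:{lineno}: empty pathway name or gene set")
        if name in pathways:
            raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
        pathways[name] = genes
    if not pathways:
        raise FormatError(f"{path}: no pathways found")
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def write_modules(states: Sequence[ModuleState], path: str | Path) -> None:
    """Write predicted modules as ``disease_id, protein_id, role`` rows in
    deterministic (disease, protein) order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_id\tprotein_id\trole\n")
        for state in sorted(states, key=lambda s: s.disease_id):
            for protein in sorted(state.module):
                role = "seed" if protein in state.seed else "predicted"
                fh.write(f"{state.disease_id}\t{protein}\t{role}\n")


def read_modules(path: str | Path) -> list[ModuleState]:
    """Read back a modules file written by :func:`write_modules`."""
    seeds: dict[str, set[str]] = {}
    predicted: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected three columns")
        disease, protein, role = (f.strip() for f in fields)
        if role == "seed":
            seeds.setdefault(disease, set()).add(protein)
            predicted.setdefault(disease, set())
        elif role == "predicted":
            predicted.setdefault(disease, set()).add(protein)
            seeds.setdefault(disease, set())
        else:
            raise FormatError(f"{path}:{lineno}: unknown role {role!r}")
    states = []
    for disease in sorted(seeds):
        if not seeds[disease]:
            raise FormatError(f"{path}: disease {disease!r} has no seed proteins")
        states.append(
            ModuleState(
                disease,
                frozenset(seeds[disease]),
                seeds[disease] | predicted[disease],
            )
        )
    return states


def write_trace(trace, path: str | Path) -> None:
    """Write an annealing trace as TSV (temperature, objective, best,
    accepted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# temperature\tobjective\tbest_objective\taccepted\n")
        for rec in trace:
            fh.write(
                f"{rec.temperature:.10g}\t{rec.objective:.10g}\t"
                f"{rec.best_objective:.10g}\t{rec.accepted}\n"
            )


@dataclass
class RunBundle:
    """Everything one optimization run needs, loaded and cross-restricted.

    After loading, the disease universe is the set of diseases that both
    have a non-empty largest connected component in the network and appear
    in the phenotypic similarity source; association tables are restricted
    to network proteins.
    """

    network: ProteinNetwork
    known_associations: dict[str, set[str]]
    phen: PhenotypeSimilarityMatrix
    seeds: dict[str, frozenset[str]]
    gold: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    pathways: dict[str, set[str]] | None = None
    dropped_diseases: list[str] = field(default_factory=list)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return self.phen.disease_ids

    def initial_states(self) -> list[ModuleState]:
        return [ModuleState(d, self.seeds[d]) for d in self.disease_ids]


def load_dataset(
    network_path: str | Path,
    associations_path: str | Path,
    phenotype_sim_path: str | Path,
    gold_paths: Mapping[str, str | Path] | None = None,
    pathways_path: str | Path | None = None,
    similarity_kind: str = "auto",
) -> RunBundle:
    """Load and cross-restrict a full dataset.

    Association rows whose protein is absent from the network are dropped
    (with a logged count); the disease universe is the intersection of
    diseases with a non-empty seed and diseases in the similarity source.
    """
    network = read_network(network_path)
    raw_assoc = read_associations(associations_path)
    phen = read_phenotype_similarity(phenotype_sim_path, kind=similarity_kind)

    known: dict[str, set[str]] = {}
    dropped_proteins = 0
    for disease, proteins in raw_assoc.items():
        present = {p for p in proteins if p in network}
        dropped_proteins += len(proteins) - len(present)
        if present:
            known[disease] = present
    if dropped_proteins:
        logger.info(
            "dropped %d association(s) with proteins absent from the network",
            dropped_proteins,
        )

    seeds: dict[str, frozenset[str]] = {}
    dropped: list[str] = []
    phen_diseases = set(phen.disease_ids)
    for disease in sorted(raw_assoc):
        lcc = largest_connected_component(raw_assoc[disease], network)
        if not lcc or disease not in phen_diseases:
            dropped.append(disease)
            continue
        seeds[disease] = frozenset(lcc)
    if not seeds:
        raise FormatError("no disease has both a connected seed and a similarity entry")
    universe = tuple(sorted(seeds))
    if dropped:
        logger.info(
            "excluded %d disease(s) without a seed or similarity entry: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )

    gold: dict[str, dict[str, set[str]]] = {}
    for name, gpath in (gold_paths or {}).items():
        table = read_associations(gpath)
        gold[name] = {
            d: {p for p in ps if p in network}
            for d, ps in table.items()
            if d in seeds and any(p in network for p in ps)
        }
    pathways = read_gmt(pathways_path) if pathways_path else None

    return RunBundle(
        network=network,
        known_associations={d: known.get(d, set()) for d in universe},
        phen=phen.restrict(universe),
        seeds=seeds,
        gold=gold,
        pathways=pathways,
        dropped_diseases=dropped,
    )
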