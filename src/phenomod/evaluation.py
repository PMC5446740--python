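"""Quantitative validation of predicted disease modules.

Covers hypergeometric over-representation tests with Benjamini–Hochberg FDR
control, seed-pruning cross-validation, recovery of held-out disease–protein
associations, pathway (GMT) enrichment, coherence of novel predictions with
seed-enriched pathways, and a random connected-module null model for
empirical p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import ProteinNetwork, cascade_remove, frontier, is_connected_in

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_fdr",
    "prune_seed_for_cv",
    "recovery_rate",
    "enrich_predictions",
    "pathway_enrichment",
    "predicted_coherence",
    "random_connected_expansion",
    "empirical_p_value",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric over-representation test.

    ``k`` hits among ``n`` draws from a population of ``N`` containing ``K``
    marked elements; ``q_value`` is the BH-adjusted p-value (equal to
    ``p_value`` before correction).
    """

    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    label: str = ""

    def adjusted(self, q: float) -> "EnrichmentResult":
        return EnrichmentResult(self.k, self.K, self.n, self.N, self.p_value, q, self.label)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the population size, ``K`` the marked sub-population, ``n`` the
    number of draws and ``k`` the observed hits.
    """
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, in the original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _enrichment(k: int, K: int, n: int, N: int, label: str = "") -> EnrichmentResult:
    p = hypergeometric_tail(k, K, n, N)
    return EnrichmentResult(k, K, n, N, p, p, label)


# ---------------------------------------------------------------------------
# seed-pruning cross-validation


def prune_seed_for_cv(
    seed: set[str],
    network: ProteinNetwork,
    rng: np.random.Generator,
    min_fraction: float = 0.10,
) -> tuple[set[str], set[str]] | None:
    """Prune a connected seed for cross-validation.

    Repeatedly removes a randomly chosen protein together with every protein
    thereby disconnected, until at least ``min_fraction`` of the original
    seed has been removed.  A uniformly chosen anchor protein is fixed first
    and never removed, which guarantees the pruned seed stays connected and
    non-empty; cascades are computed relative to the anchor.

    Returns ``(pruned_seed, removed_set)``, which partition the original
    seed, or ``None`` for size-1 seeds (dismissed from the analysis).
    """
    seed = set(seed)
    if len(seed) < 2:
        return None
    if not is_connected_in(seed, network):
        raise ValueError("seed must be connected")
    target = math.ceil(min_fraction * len(seed))
    anchor = sorted(seed)[rng.integers(len(seed))]
    pruned = set(seed)
    removed: set[str] = set()
    while len(removed) < target:
        candidates = sorted(pruned - {anchor})
        if not candidates:  # only the anchor is left; nothing more removable
            break
        victim = candidates[rng.integers(len(candidates))]
        pruned = cascade_remove(pruned, {anchor}, victim, network)
        removed = seed - pruned
    return pruned, removed


def recovery_rate(
    predicted: Mapping[str, set[str]], held_out: Mapping[str, set[str]]
) -> float:
    """Fraction of held-out (disease, protein) associations present in the
    predictions."""
    total = sum(len(v) for v in held_out.values())
    if total == 0:
        raise ValueError("no held-out associations to recover")
    hits = sum(
        len(set(held_out[d]) & set(predicted.get(d, set()))) for d in held_out
    )
    return hits / total


# ---------------------------------------------------------------------------
# gold-standard enrichment


def enrich_predictions(
    predicted: Mapping[str, set[str]],
    gold: Mapping[str, set[str]],
    universe: set[str],
) -> tuple[EnrichmentResult, list[EnrichmentResult]]:
    """Hypergeometric enrichment of predicted associations in a gold standard.

    The global test pools all (disease, protein) pairs over the shared
    disease set: the population is ``|universe| * #diseases`` pairs, the
    marked sub-population the gold associations, the draws the predicted
    associations.  Per-disease tests use that disease's gold set as the
    marked population within ``universe``; their p-values are BH-corrected
    across diseases.
    """
    if not universe:
        raise ValueError("empty universe")
    diseases = sorted(set(predicted) & set(gold))
    per_disease: list[EnrichmentResult] = []
    pooled_k = pooled_K = pooled_n = 0
    N = len(universe)
    for d in diseases:
        pred = set(predicted[d]) & universe
        mark = set(gold[d]) & universe
        res = _enrichment(len(pred & mark), len(mark), len(pred), N, label=d)
        per_disease.append(res)
        pooled_k += res.k
        pooled_K += res.K
        pooled_n += res.n
    qs = bh_fdr([r.p_value for r in per_disease])
    per_disease = [r.adjusted(q) for r, q in zip(per_disease, qs)]
    pooled = _enrichment(
        pooled_k, pooled_K, pooled_n, N * len(diseases), label="pooled"
    )
    return pooled, per_disease


def pathway_enrichment(
    modules: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> tuple[dict[str, list[EnrichmentResult]], dict[str, int]]:
    """Per-(disease, pathway) hypergeometric enrichment with per-disease FDR.

    Returns the full result table keyed by disease and, per disease, the
    count of pathways enriched at ``q < alpha``.
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    names = sorted(pathways)
    results: dict[str, list[EnrichmentResult]] = {}
    enriched_counts: dict[str, int] = {}
    for d in sorted(modules):
        mod = set(modules[d]) & universe
        rows = []
        for name in names:
            genes = set(pathways[name]) & universe
            rows.append(_enrichment(len(mod & genes), len(genes), len(mod), N, name))
        qs = bh_fdr([r.p_value for r in rows])
        rows = [r.adjusted(q) for r, q in zip(rows, qs)]
        results[d] = rows
        enriched_counts[d] = sum(1 for r in rows if r.q_value < alpha)
    return results, enriched_counts


def predicted_coherence(
    predicted: set[str],
    reference_pathways: Mapping[str, set[str]],
    universe: set[str],
) -> EnrichmentResult | None:
    """Do novel predictions fall into pathways already enriched in the seed?

    Tests the overlap between the predicted proteins and the union of the
    reference (seed- or known-protein-enriched) pathways.  Returns ``None``
    when the reference union is empty (no defined test).
    """
    union: set[str] = set()
    for genes in reference_pathways.values():
        union |= set(genes)
    union &= universe
    if not union:
        return None
    pred = set(predicted) & universe
    return _enrichment(len(pred & union), len(union), len(pred), len(universe))


# ---------------------------------------------------------------------------
# random connected-module null model


def random_connected_expansion(
    seed: set[str],
    target_size: int,
    network: ProteinNetwork,
    rng: np.random.Generator,
    max_iter: int | None = None,
) -> set[str]:
    """Grow a random connected module of exactly ``target_size`` around a seed.

    Performs a random add/remove walk — additions drawn from the module
    frontier, removals of random non-seed proteins with cascade removal —
    halting the first time the module size equals ``target_size``.  Used to
    build size-matched null modules for empirical p-values.
    """
    seed = set(seed)
    if not is_connected_in(seed, network):
        raise ValueError("seed must be connected")
    if target_size < len(seed):
        raise ValueError("target size smaller than the seed")
    if target_size == len(seed):
        return seed
    component = network.component_of(next(iter(seed)))
    if target_size > len(component):
        raise ValueError(
            f"target size {target_size} exceeds the seed's component "
            f"({len(component)} proteins)"
        )
    module = set(seed)
    if max_iter is None:
        max_iter = 1000 * target_size
    for _ in range(max_iter):
        add_pool = frontier(module, network)
        remove_pool = module - seed
        want_add = bool(rng.integers(2))
        if want_add and not add_pool:
            want_add = False
        elif not want_add and not remove_pool:
            want_add = True
        if want_add and add_pool:
            items = sorted(add_pool)
            module.add(items[rng.integers(len(items))])
        elif remove_pool:
            items = sorted(remove_pool)
            module = cascade_remove(module, seed, items[rng.integers(len(items))], network)
        if len(module) == target_size:
            return module
    raise RuntimeError("random expansion did not reach the target size")


def empirical_p_value(observed: float, null_scores: Iterable[float]) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + #null)."""
    nulls = list(null_scores)
    if not nulls:
        raise ValueError("need at least one null score")
    ge = sum(1 for s in nulls if s >= observed)
    return (1 + ge) / (1 + len(nulls))
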