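# Methods

## Model

`phenomod` infers one connected disease module per disease, for all
diseases jointly. The data are (i) an undirected simple PPI network over
opaque protein identifiers, (ii) a disease → protein association catalog,
and (iii) a symmetric phenotypic similarity matrix `PhenSim ∈ [0,1]^{D×D}`
(given directly as pairwise values, or computed as cosine similarity of
non-negative symptom-count vectors). Each disease is seeded with the
largest connected component (LCC) of its known proteins projected into the
network; the seed is immutable. The optimizer minimizes

    E(M_1, …, M_D) = Σ_{i<j} (PhenSim_ij − Jaccard(M_i, M_j))²

over connected supersets `M_i` of the seeds. The underlying assumption is
that phenotypic similarity reflects shared molecular mechanism, so the
pairwise overlap structure of the true modules should reproduce the
phenotypic similarity structure. Diseases with no protein in the network,
or absent from the similarity source, are excluded before optimization and
listed in the run log.

LCC ties (several maximum-size components) are broken by choosing the
component containing the lexicographically smallest protein identifier —
deterministic and independent of any library's iteration order.

## Optimizer

Simulated annealing with Metropolis acceptance and a geometric cooling
schedule `T_0 = max_temp`, `T ← α·T`, stopping before `T < min_temp`, with
`steps_per_temp` proposals per level. Each proposal:

1. pick a disease uniformly at random;
2. pick add or remove with probability ½ each (falling back to the other
   action if the chosen pool is empty; skip if both are empty);
3. **add**: a protein drawn uniformly from the module frontier (neighbors
   of module members outside the module);
   **remove**: a non-seed module member drawn uniformly, deleted together
   with every protein thereby disconnected from the seed (cascade
   removal — "connected to the seed" means reachable from a seed protein
   via paths inside the remaining module);
4. accept with probability 1 if the objective does not increase, else
   `exp(−ΔE/T)`.

Moves therefore never break the invariant that a module is a connected
superset of its seed (a debug flag, `validate_moves`, re-checks it after
every accepted move). A single NumPy `Generator` seeded from the
configuration drives every random choice — disease, action, protein,
acceptance — and candidate pools are sorted before drawing, so runs are
bit-reproducible. Counting convention: `steps_per_temp` counts proposals,
not accepted moves.

`ΔE` is computed incrementally over the `D−1` pairs involving the
perturbed disease (O(D·|module|) per step instead of O(D²)); the running
total is verified against a full recomputation every `check_every`
temperature levels (default 100) with a 1e-6 drift tolerance, and resynced
there. The returned solution is the final state by default; `report_best`
returns the best-so-far snapshot instead. An optional `snapshot_every`
records full module snapshots in the trace for convergence analyses.

Default parameters: `max_temp = 5`, `min_temp = 1e-25`, `α = 0.995`,
`steps_per_temp = 200` — the published operating point for full-scale
interactome runs (~11,800 temperature levels). The `fast` preset
(`min_temp = 1e-4`, `α = 0.95`, `steps_per_temp = 100`, ~210 levels) is the
schedule used throughout the test suite and the acceptance script; on the
reference benchmark below it converges in about one second.

Degenerate conventions: `Jaccard(∅, ∅) := 0` (keeps the function total;
unreachable in normal runs since seeds are non-empty); the objective sums
strictly over `i < j`.

## Evaluation battery

- **Enrichment**: one-sided hypergeometric upper tail `P(X ≥ k)`
  (over-representation only). For gold-standard association tests the
  population is the proteins present in both the network and the gold
  source; for pathway tests it is all network proteins. The global
  ("pooled") gold-standard test pools all (disease, protein) pairs:
  population `|universe| × D` pairs, marked = gold associations, draws =
  predicted associations. This pooled 2×2 construction is the natural
  reading of a single global association test and is the one implemented.
- **FDR**: Benjamini–Hochberg. Scope: across pathways within each disease
  for pathway enrichment; across diseases for per-disease gold-standard
  enrichment. Significance threshold 0.05 throughout.
- **Seed-pruning cross-validation**: per disease, repeatedly remove a
  random seed protein plus everything it disconnects until at least 10% of
  the original seed is gone; re-optimize from the pruned seeds; report the
  fraction of held-out (disease, protein) associations that reappear as
  predictions. Size-1 seeds are dismissed. Because unconstrained cascades
  could empty or disconnect a seed, a uniformly chosen anchor protein is
  fixed first and never removed, and cascades are computed relative to it —
  the minimal mechanism that guarantees a connected, non-empty pruned seed.
- **Coherence**: pathways enriched in the seed (or known) proteins form a
  reference union; the novel predictions are tested hypergeometrically
  against membership in that union. An empty union yields "no defined
  test" (`None`) rather than a p-value.
- **Null modules**: size-matched random connected expansions of the same
  seed (random add/remove walk halting at the target size). Empirical
  p-values use the add-one convention `(1 + #{null ≥ obs}) / (1 + #null)`,
  so 100 replicates bound p below by 1/101.

## Synthetic benchmark

The generator emulates the statistical structure the objective assumes:

- **Background network**: a uniform random attachment tree (guaranteeing
  connectivity) plus `extra_edge_factor · n_proteins` uniformly random
  extra edges (default factor 2, mean degree ≈ 6). A `degree_skew` option
  attaches edges preferentially to high-degree nodes for hub-dominated
  topologies.
- **Planted modules**: diseases are assigned round-robin to
  `overlap_groups` groups; each group grows a shared connected core, and
  each disease grows its module from the core by uniform frontier
  expansion to a Poisson(`mean_module_size`) size.
- **Seeds**: a connected subset of the planted module (fraction
  `seed_fraction`), grown from a random core protein and restricted to the
  module.
- **Phenotypic similarity**: exactly the pairwise Jaccard similarity of
  the planted modules, plus optional symmetric Gaussian noise clipped to
  [0, 1] (`noise_sd`). At zero noise and `seed_fraction = 1` the seeds are
  already optimal (objective 0).

**Core size and identifiability.** The shared core defaults to 2/3 of the
mean module size (`core_fraction`). This is deliberate: a pairwise-Jaccard
objective constrains the *shared* content of group-mates but says nothing
about which unique proteins fill the remainder, so planted proteins
outside the core are unidentifiable in principle. Recovery of the planted
truth is driven by the cores, and only happens when the within-group
target similarities exceed the initial seed–seed similarity — otherwise
minimizing the objective pushes modules apart rather than back onto the
planted cores. With `core_fraction = 2/3`, within-group targets (~0.5) sit
above the seed baseline (~0.4) and the optimizer must re-assemble the
cores to meet them.

**What the benchmark does not emulate**: scale-free interactome topology
(unless `degree_skew` is set), literature bias in association catalogs,
symptom vectors (similarity is generated directly), or identifier mapping
noise. Passing the recovery tests therefore demonstrates that the
optimizer exploits phenotype-similarity structure correctly, not that
real-data recovery rates will match.

## Reference configuration and problem sizes

The test suite and the acceptance script run the benchmark at 500
proteins, 20 diseases, 5 overlap groups, mean module size 15, seed
fraction 0.4, zero noise, with the `fast` schedule, across ten independent
generator/optimizer seeds. These sizes give each disease a non-trivial
search space while keeping a full ten-run sweep around ten seconds.
Measured on this configuration: the objective drops in 10/10 runs (by
~97% on average), the mean module-to-planted Jaccard rises above the
seed-to-planted baseline in 10/10 runs (~0.43 → ~0.52), the Spearman
correlation between the objective and the pooled enrichment of predictions
against the planted truth along the trace is strongly negative (~−0.9),
and seed-pruning cross-validation recovers roughly half of the held-out
associations.

## Limitations

- The objective's optimum is not unique: any module configuration with the
  right pairwise intersection/union sizes is equivalent, so individual
  protein predictions outside shared cores carry less evidence than the
  recovered overlap structure.
- Pearson correlation between module and phenotypic similarity is reported
  as a diagnostic only; the optimizer never targets it directly.
- The annealer is single-chain: no restarts, parallel tempering, or
  adaptive schedules.
- Full-scale runs (hundreds of diseases on a ~14k-protein interactome with
  the default schedule) take hours on one CPU; the package does not
  parallelize them.
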