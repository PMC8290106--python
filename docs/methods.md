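# Methods

`pycatchr` implements a remote-homology detection and classification
workflow for deeply divergent paralogous protein families — the situation
typified by the CATCHR multisubunit tethering complexes (exocyst, COG, GARP,
DSL1), whose ~22 subunit families descend from one ancestral tetramer yet
share pairwise ortholog identities in the twilight zone. The package couples
the analysis pipeline to a generative simulator so that every stage can be
validated against a known gene history.

## The generative model

The simulator encodes the ancestral-tetramer scenario as a rooted tree over
subunit "units": an ancestral dimer (one body-forming, one arm-forming
protein) duplicates into a tetramer of four classes (g51, g52, g53, g54),
and the tetramer is then duplicated repeatedly into five full complexes plus
one half complex that retains only its g53/g54 subunits (the DSL1 analogue).
Depths are in expected substitutions per site:

| parameter | default | meaning |
|---|---|---|
| `class_split_depths` | g52 26, g51 16, g53/g54 10 | inter-class splits; g53/g54 shallowest, g52 most remote |
| `complex_split_depths` | 5.8, 5.4, 5.0, 4.6, 4.2 | tetramer duplications into complexes B, C, H(half), D, E |
| `species_tree_depth` | 6.0 | root-to-tip depth of the shared species tree |
| `n_taxa` | 7 | three seed taxa, each with one shallow partner, plus one deep unpaired lineage |
| `p_loss`, `p_lineage_dup` | 0.12, 0.04 | per-taxon per-family loss and duplication probabilities |

The species panel is deliberately structured the way real remote-orthology
panels are: every deeply diverged lineage is represented by a pair of
related proteomes (pair split at 15% of the tree depth), so iterative
profile enrichment has a foothold, while the lineages themselves sit at
twilight-zone distances (ladder decay 0.93, deep splits ≈ 4.8–6.0, i.e.
pairwise path lengths ≈ 10–12 substitutions/site). One lineage is a single
deep proteome. An odd panel keeps the ortholog-identity median pinned to the
deep pairs rather than to the midpoint of a bimodal mixture.

Sequence evolution is a per-branch replacement process: a site with rate `r`
is replaced over a branch of length `d` with probability `1 − exp(−r·d)`,
the replacement drawn from a BLOSUM62-derived conditional distribution
(`P(b|a) ∝ π_b·2^{s_ab/2}`). Site rates are drawn per *block* (geometric
block length, mean 15) and inherited through the entire gene tree: a
fraction `core_block_frac = 0.10` of blocks forms a slow structural core
(`core_block_rate`, default calibrated near 0.10) and the remainder draws
gamma(shape 1.0) rates. Rate-block sharing across the whole superfamily is
the generative analogue of conserved helical-bundle packing cores, and it is
what keeps profile methods informative after average identity has decayed
into the twilight zone; the gamma bulk controls how fast ortholog identity
decays. Indels are Poisson along branches (rate 0.0015/site, geometric
lengths of mean 3), excluded from the coiled-coil segment, and every residue
carries an ancestral site id so tests can score alignments against the true
site genealogy.

The confounder: every family inherits the same N-terminal 56-residue heptad
coiled-coil template, evolving at one quarter of the body rate with
replacements drawn from heptad-position-specific residue preferences. Its
stationary distribution is the biased heptad composition itself, so
cross-family coiled coils never decay to background — precisely the
"spurious shared signal" that motivates masking.

What the simulator does *not* emulate: real domain gains/losses and
architecture variation, compositional biases beyond the coiled coil,
site-specific amino-acid profiles (replacement is matrix-conditional, not
site-specific), rate variation across lineages, and alignment-fragmenting
low-complexity regions. Passing tests therefore demonstrate that the
workflow's logic behaves as intended under a faithful but idealized
divergence process, not that it reaches any particular sensitivity on real
proteomes.

## Coiled-coil scoring

A COILS-style scorer: for each window (28 residues; shorter sequences use a
proportionally shortened window) the best of the seven heptad frames is
taken, a frame's score being the geometric mean of position-specific residue
propensities; a residue's score is the best over covering windows, and
scores map to probabilities through a two-Gaussian (coil vs globular)
decision rule with a 30:1 globular prior. The propensity table is synthetic
— constructed from canonical heptad preferences (hydrophobic a/d core,
charged e/g flanks) — and shipped as versioned package data; the Gaussian
parameters were calibrated once against windows sampled from the table's own
emission model and from background composition. Masking replaces flagged
residues with 'X' (zero profile counts) rather than deleting them, keeping
coordinates comparable between masked and unmasked runs.

## Alignment and profiles

Global and local alignment use affine gaps (run of length k costs
`open + (k−1)·extend`) with deterministic traceback (diagonal > up > left).
Profiles are pseudocounted column frequency models,
`f = (counts + w·background)/(n + w)` with `w = 0.1`; gaps and 'X' are
excluded from counts and masked columns carry plain background. Column
scores are half-bit log-odds, `s(i,j) = 2·log2(Σ_a f1_ia f2_ja / b_a)`, and
local profile–profile alignment scales gap costs by one minus the mean gap
fraction of the flanking columns. Profiles are built from alignments whose
majority-gap columns (>50%) are removed; the exported MSAs keep the
conventional 80% trimming threshold.

Progressive alignment uses an average-linkage guide tree on global-alignment
identities and merges groups by profile–profile global alignment. Merge
steps use heavier pseudocounts (w = 1) and stiffer gaps (16/2): with sparse
one-hot columns and the pairwise defaults, a global merge prefers staggered
gap-column detours over aligning genuinely homologous but diverged blocks —
a failure mode caught by the site-genealogy oracle in the test suite.

## Significance

Two calibrations, both against column-shuffle nulls of the profile (the
shuffle preserves composition, so compositional confounders are absorbed by
the null):

* **Empirical rank p** — `p = (1 + #{null ≥ obs})/(n_shuffles + 1)`; used
  for the similarity network, where the contract is `p < 1e−2` and the
  shuffle count (default 100) makes that threshold attainable exactly.
* **Gumbel tail** — a method-of-moments extreme-value fit to the null
  scores. The rank p cannot resolve anything below its floor, so search
  e-values (`e = p·n_targets`, thresholds down to 1e−5) and the calibrated
  distances used for cladograms (`w = min(−log10 p, 20)`, mirroring the
  heatmap's 1e−20 cap) use the tail fit. This is the same family of
  calibration that HMM search tools rely on.

Null sampling for profile searches uses 48 column-shuffled alignments
against a deterministic sample of database sequences; pairwise searches
shuffle the query residues. All shuffle seeds derive from the run seed and
stable identifiers, so reruns are byte-identical.

## Orthology workflow

Per seed taxon and family: (1) iterative profile enrichment against the
pooled proteomes, three rounds at inclusion e ≤ 1e−5 (after the first
full-database scan, subsequent rounds rescan only plausible candidates —
p < 0.5 or top 40 — with e-values still Bonferroni-corrected over the full
database, mirroring the accelerated filter cascades of HMM search tools;
iteration stops early at a fixed point); (2) forward best hit per target
proteome at e ≤ 1e−3, ties broken by longer alignment then id; (3)
reciprocal validation: a profile enriched from the forward hit (four rounds
at 1e−2) searches the seed proteome with no threshold and must return the
seed at rank one; (4) an independent sequence-level reciprocal search
(global alignment, e ≤ 1e−2 forward / 1e−3 back, query coverage strictly
above 40%). Searches run on coiled-coil-masked sequences.

The three seed analyses and two methods are combined by voting per
(family, taxon): the most widely validated target wins; ties prefer targets
backed by the sequence-level method (validated sequence hits are
family-specific, whereas profiles enriched with ortholog mixtures mis-rank
co-ortholog e-values); the reported e-value is the best among the winner's
supporters. Validated disagreement is flagged `conflict` — the
machine-readable stand-in for manual curation, optionally overridden by a
curation file. Additional reciprocally-valid hits in the same proteome are
reported as co-orthologs (lineage duplications).

## Classification layers

* **Consensus cladograms and replicated clusters.** Per seed taxon, family
  profiles are rebuilt from *that analysis's own* recovered orthologs and
  compared all-vs-all. Average-linkage cladograms over the calibrated
  distances (`D = 20 − min(−log10 p, 20)`, best direction per pair) feed a
  majority-rule consensus with per-clade congruence labels. For the flat
  cluster summary, each analysis is partitioned by modularity on its own
  significance graph, and evidence accumulation keeps the family pairs
  co-clustered in ≥2 of the 3 analyses; the replicated clusters are the
  non-singleton connected components of those pairs (families that never
  co-cluster reproducibly stay unassigned). Because per-analysis profiles
  carry only one seed's ortholog subset, they are less sensitive than the
  combined-profile network below — so an individual analysis may blur the
  two shallowest classes while the replicated consensus still separates
  them.
* **Similarity network.** Families are represented by profiles built from
  their combined ortholog alignments (masked and unmasked variants). Edges
  connect pairs where either directed hit has empirical p < 1e−2 (weight
  `min(−log10 p, 20)`); a variant network additionally requires alignment
  length > 300 and membership in the query's top-4 hits. Communities come
  from greedy (CNM) modularity maximization — deterministic, with Q
  recomputed from scratch — and any community containing at least two of
  the consensus clusters is re-clustered on its induced subgraph, which
  separates classes whose distinction the full network blurs (the g53/g54
  phenomenon: in the full graph the resolution limit of modularity merges
  two internally dense classes joined by borderline edges; on the induced
  subgraph the same edges are too weak to hold them together).

## Numerical and procedural choices

* Identity/similarity statistics (the ortholog-distribution report) use
  gap penalties 20/2 rather than the 10/1 alignment defaults: identity is
  defined over gapless aligned pairs, and cheap gap extension lets a global
  aligner chase coincidental identities, inflating *unrelated* 700-residue
  pairs to ~24% "identity"; at 20/2 the unrelated floor sits near 13–14%,
  so twilight-zone orthologs are measured against an honest baseline.
* All DP tracebacks are deterministic; every stochastic step (shuffles,
  simulation, sampling) derives from the run seed; thread count never
  affects results.
* Degenerate inputs: empty optimal local alignments give score 0 with empty
  spans and p = 1; all-gap profile columns fall back to background with a
  warning; single-sequence inputs are their own alignments and single-leaf
  trees their own cladograms.
* Scaled-down problem sizes (7 proteomes of ~22 proteins, 700-residue
  sequences, 100-shuffle networks) were chosen so that a complete run is
  feasible on a single CPU while every stage still operates in its intended
  regime; the calibration of the generator (species depth, core fraction
  and rate) targets the published characterization of the system: median
  ortholog identity below ~20%, four recoverable classes, and a
  blurred-then-separable g53/g54 pair.

## Known limitations

* The engine is a gap-annotated frequency-profile aligner, not a full
  profile HMM with insert/delete states; it sits behind a narrow interface
  (`ProfileSearch`) so a genuine HMMER/HH-suite adapter could be swapped in.
* Empirical significance is honest but coarse at small shuffle counts; very
  small p-values are extrapolations of a two-parameter tail fit.
* The consensus-cladogram stage assumes the three analyses share a leaf
  set; families missing a seed protein in any seed taxon are excluded from
  that stage (they still appear in the network).
* Modularity maximization is greedy and resolution-1.0 only; sub-clustering
  is the provided remedy for resolution-limit merges.
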