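# Methods

This note documents the models, statistics and design choices behind
`nutriconnect`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under what assumptions,
which knobs matter, and what the synthetic studies do and do not show.

## 1. Differential expression by rank product

Replicate case/control datasets of one entity are combined
nonparametrically. Per dataset the unpaired log₂ fold change
`fc_g = mean(case) − mean(control)` is ranked twice — descending for the
up direction, ascending for down, average ranks on ties — and
`RP_g = (∏_i r_{g,i})^(1/k_g)` where `k_g` counts the datasets containing
gene *g*. Genes present in fewer than half the datasets are excluded.
Being rank-based, the statistic is unchanged by any positive affine
rescaling of a dataset's values, which is what justifies pooling
heterogeneous platforms.

Significance: the null pools RP values from `n_perm` independent uniform
permutations of each dataset's rank vector (`n_genes × n_perm` null
values), `p_g = (#null ≤ RP_g + 1)/(n_genes·n_perm + 1)`, and the
false-discovery proportion is `pfp_g = p_g · n_genes / rank(RP_g)`.
Up/down calls use pfp ≤ 0.05; a dual-significant gene goes to the
direction with the smaller pfp (tie: the sign of its combined fold
change) so the sets stay disjoint. Both directions share one permutation
pool (same derived seed), which makes case/control label reversal swap
the up and down sets exactly.

Defaults: `n_perm = 200` for the rank-product pfp. The per-gene null is
`n_genes`-fold larger than the number of permutations, so 200
permutations already give ~2·10⁵ null values at the default universe
size. Detection power falls steeply with the number of replicate
datasets: with a single dataset the pfp of the rank-r gene is ~1 by
construction, with two datasets only the first handful of genes can
reach pfp ≤ 0.05, and three or more datasets (the default) give the
intended behavior. Fold changes are unpaired; expression compendia
case/control arms are typically independent samples.

## 2. Enrichment-score connectivity

Tag sets per query: significant DE genes per direction, ordered by
|logfc|, capped at 250 per direction, minimum 5 (entities below the
minimum are unscorable and flagged). The tag statistic is the classic
connectivity-mapping KS running-sum on 1-based positions (see README for
the formula); a tag set covering the entire list carries no positional
information and is defined as 0. The directional score combines the two
tag sets as `(ks_up − ks_down)/2` with the same-sign-zero rule: a
signature whose up and down sets drift to the same end of the reference
list is not a directional signal. The pair score averages the two
directions (query tags in reference list, and vice versa).

Significance: per pair, `n_perm = 1000` random query signatures with the
observed tag-set sizes are drawn uniformly without replacement from the
reference list and combined identically; the two-sided p is
`(#{|es_null| ≥ |es_obs|} + 1)/(n_perm + 1)`, BH-corrected within each
query-entity batch (diet-disease and drug-disease pairs are corrected
separately, since they form separate screens). Classes: anti-correlated
(`es < 0`, FDR < 0.05), correlated (`es > 0`, FDR < 0.05), otherwise
not-significant.

Disease clustering uses `1 − Pearson` over ES profile rows, average
linkage, Newick export. Missing profile entries are imputed as 0 for
clustering only; a zero-variance row is placed at the maximum distance 2
and flagged. Bootstrap support values are out of scope.

## 3. Pathway space

Over-representation is the one-sided hypergeometric upper tail
`P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, BH-FDR < 0.05, with the universe
taken as the genes present in the entity's own ranked list (the genes
the experiment could have called). For anti-correlated pairs only,
entities are grouped by (disease class, diet|drug); the score matrix
holds the proportion of each group's entities enriched for each pathway.
PCA centers columns without unit-variance scaling — the entries are
already commensurable proportions — via SVD with a deterministic sign
convention (largest-magnitude loading positive). A variable's
contribution is its squared loading summed over PC1–PC2; the top 30 are
reported. Disease-related pathways are the intersection of entity and
disease enrichment sets, ranked per disease by how many anti-correlated
entities share them.

## 4. Network proximity

Analysis is restricted to the interactome's largest connected component;
hop distances come from a cached sparse all-pairs shortest-path matrix.
`d_c(T, S)` averages, over the entity's DE genes `T`, the distance to
the nearest disease-module gene in `S`; unmappable members are dropped
and counted. The null redraws **both** sets degree-matched: nodes are
binned by degree, bins merged upward until each holds ≥ `bin_min = 100`
nodes, and each draw samples without replacement within bins
(`n_random = 1000` draws). If a draw needs more nodes than its bin
holds, the bin is topped up from the global pool; graphs smaller than
`bin_min` fall back to a single bin with a warning.
`z_c = (d_c − mean_null)/sd_null`; `z_c < 0` is proximal, and the
boundary `z_c = 0` is labelled distant. A degenerate null
(`sd_null = 0`) flags the result rather than producing an infinite z.

## 5. Chemical similarity

Morgan circular fingerprints, radius 2 (ECFP4-equivalent, the community
default) hashed to 2048 bits, binary; Tanimoto = |a∩b|/|a∪b| with the
both-empty case defined as 0 and flagged. A food-drug pair is "similar"
when any of its compound pairs reaches 0.4. Pairs are compared on their
shared anti-correlated disease counts with a two-sided Wilcoxon
rank-sum; for combined group sizes ≤ 12 the p-value is computed exactly
by enumerating all label assignments (correct under ties), otherwise by
the tie-corrected normal approximation. No tautomer standardization or
3D similarity is attempted.

## 6. Synergy

Core genes of a food pair: genes significantly DE in at least one of the
two foods (restricted to the shared ranked universe). Scores:

* rank 2 — `(concordant − discordant both-DE genes)/|core|`, normalized
  by the core size so pairs of different sizes are comparable;
* rank 4 — Pearson correlation of the two logfc vectors on the core
  (≥ 3 genes, non-degenerate variance);
* rank 9 — Borda (mean-rank) aggregation of the expression correlation,
  the Jaccard overlap of enriched pathway sets, and the Jaccard overlap
  of enriched function-term sets.

Calls use a per-pair permutation null that shuffles each food's
direction-call vector over the core gene identities (`n_perm = 1000`);
a pair is synergistic when its rank-2 score is positive with upper-tail
p < 0.05. The gold standard contains food pairs sharing at least one
disease association whose joint reference count over shared diseases is
strictly greater than 10 (the sum is read jointly over both foods).
Recovery for the score-only methods (rank 4/9) is evaluated on their
top-k pairs with k set to the number of rank-2 calls, for comparability.

## 7. The synthetic study generator

The generator emulates the data substrate the pipeline is designed for,
with planted truth:

* **Expression model** — per dataset, controls are i.i.d.
  `Normal(baseline_mean = 8, baseline_sd = 0.5)` per gene on the log₂
  scale; cases add ±`effect_size = 1.5` on signature genes plus
  `Normal(0, noise_sd = 0.5)` noise. This is the simplest two-group
  shift model under which fold-change ranking and the rank product
  behave as intended. Each entity gets 3 replicate datasets of 5 samples
  per arm.
* **Interactome** — a Barabási–Albert preferential-attachment graph
  (500 nodes, 3 edges per new node): simple, connected, heavy-tailed.
  Disease modules (20 nodes) grow by seeded random breadth-first
  expansion and are therefore connected; modules of different diseases
  are disjoint.
* **Signatures** — a disease signature is its module genes plus an equal
  number of private off-module genes, each with a random direction
  (40 genes total). Signatures of different diseases are disjoint, so
  the label of any entity-disease pair (anti-correlated / correlated /
  null) is exactly recomputable from signed-set overlap — the
  planted-label consistency invariant the tests assert. An
  anti-correlated food flips `⌈0.8·|signature|⌉` genes of its target
  disease; a correlated (risk) food copies the same share (mirroring the
  ES sign convention); every food additionally receives
  `⌈0.02·n_genes⌉` unrelated DE genes drawn from the background pool
  (genes outside all disease signatures; background genes may be shared
  between entities). Null foods are built entirely from background
  genes.
* **Synergy pairs** — defined as two foods jointly covering one
  disease's reversal with partial overlap: each member holds 70% of the
  reversed signature (overlap 40%), a choice made a priori so the
  concordant overlap clearly exceeds its permutation null at the default
  DE power. Synergy pairs get reserved diseases, and the reference table
  gives their two foods counts 8 and 7 on the shared disease (> 10
  jointly) while ordinary anti-correlated foods get count 4 (two foods
  sharing a disease sum to 8, below the gold threshold) — so the planted
  gold set equals the synergy pairs exactly.
* **Annotations** — one pathway per disease is seeded with ≥ 60% of its
  module so enrichment is detectable; the rest are random sets in the
  configured size range. A second, purely random "function" collection
  feeds the rank-9 similarity. The probe map gives each gene 1–3 probes
  with a configurable ambiguous share; the ortholog table drops a
  configurable share (default 10%) of model-organism genes; drug
  datasets are emitted as a model organism to exercise the ortholog
  path. Compounds come from a built-in library of ~30 valid SMILES of
  common small molecules, with one designated structurally identical
  food/drug compound pair.

What the generator does **not** model: platform batch effects,
array-specific intensity distributions, correlated gene-gene noise,
partially overlapping disease etiologies, or compound chemistry beyond
the fixture library. Passing tests therefore demonstrate the methods'
correctness and calibration under a clean additive model — not
performance on real compendia, where noise structure, signature overlap
and annotation bias are all harsher.

## 8. Determinism and problem sizes

One master seed deterministically derives per-stage seeds by hashing
`(master, stage name)`; all writers use fixed float formatting, so
reruns with one configuration are byte-identical (asserted in the test
suite by hashing every stage output of two independent runs). The
default study sizes (1000 genes, 10 diseases, 20 foods, 10 drugs, 3
datasets per entity; 1000 ES permutations; 1000 proximity draws) were
chosen so the full pipeline, the test suite and the acceptance script
each complete within a few minutes on one CPU while keeping every
statistical check well-powered; calibration-style tests use 200 null
pairs and binomial bands, and oracle tests use exhaustive enumeration
only at sizes where enumeration is exact and cheap.

## 9. Known limitations

* The rank-product permutation null treats genes as exchangeable within
  a dataset; genes present in only a subset of datasets get an
  approximate null (uniform ranks for the missing strata).
* The ES cap of 250 tags per direction and minimum of 5 are practical
  conventions; entities below the minimum are reported as unscored
  rather than forced.
* Degree-matched sampling guarantees the bin profile, not the exact
  degree sequence, of the observed sets.
* The synergy permutation null conditions on each food's call
  composition but not on gene-gene correlation.
* Disease "classes" in the synthetic study are round-robin labels used
  to exercise class-level statistics; they carry no biological content.
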