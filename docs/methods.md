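# Methods

`sagmetab` reimplements, as a tested library, the statistical core of a
single-cell-genomics workflow for low-biomass microbial communities:
inferring metabolic potential from highly incomplete single-cell amplified
genomes (SAGs), correcting for that incompleteness, quantifying the biases
incompleteness introduces, and summarising community structure. This note
records the models, the defaults, and the design decisions that were
genuinely open.

## Pathway calling

A genome enters the rule engine as a KO copy-count profile. Two rule kinds
mirror how metabolic potential is assessed from partial genomes:

* **Single-step reactions** list alternative gene sets. A set is satisfied
  when at least half of its non-accessory symbols are detected — the bound
  is *inclusive* (1 of 2 suffices), because a single detected subunit of a
  two-gene complex is taken as evidence given pervasive gene dropout.
  Accessory subunits never count toward the half.
* **Multi-step pathways** require the diagnostic key enzymes (all of them
  by default; catalogs may mark a definition `key_mode: any` to encode
  alternative markers) *and* a satisfied-step fraction **strictly greater**
  than the threshold (default 0.5). The asymmetry between the inclusive
  "half or more" gene-set rule and the strict ">50% completeness" step rule
  is deliberate and preserved; both follow the operational definitions the
  calling scheme is based on.

The detection count `d` of a present call is the minimum copy number across
the symbols that establish presence (complex-limited stoichiometry); for
alternative gene sets the best satisfied set wins. `d` is what the
correction consumes, so multi-copy complexes can push corrected proportions
above 100%. Defining the copy count of a complex was an open choice; the
minimum is the conservative reading and is recorded in the call provenance.

Monotonicity holds by construction: adding gene rows can only raise
detection, never revoke presence.

## Completeness-corrected proportions

With per-gene capture probability equal to a genome's completeness `c_i`
(the capture model below has exactly this marginal), `E[d_i] = c_i * k_i`
for a true copy number `k_i`, so

```
P = 100 * (1/N) * sum_i d_i / c_i
```

is unbiased for the mean copy number per genome and, for single-copy
functions, for the percent of genomes encoding the function. We weight per
genome (each SAG corrected by its own expected/observed genome-size ratio)
rather than aggregating `sum(d)/sum(c)`; both coincide at constant
completeness, and the aggregate form is available via `method="aggregate"`
for sensitivity checks. Genomes below 10% completeness are excluded by
default — the ratio `d/c` explodes as `c -> 0` and such assemblies inflate
the estimate — and the exclusion count is reported, never silent.

For multi-gene rules the estimator is *not* unbiased (presence is a
nonlinear function of captured genes); quantifying that bias is precisely
the job of the reduction simulator, and the recovery tests therefore use
single-gene pathways.

## Shared-KO strain-heterogeneity test

For `k` near-complete genomes of one species, the expected fraction of the
species' gene complement captured by *all* genomes under independent
capture is `prod(c_i)`. The observed statistic is shared/union
(Jaccard-style) over the genomes' KO sets — chosen because it is computable
from the SAGs alone; the union denominator makes the null mean slightly
exceed the product. The Monte-Carlo null captures each of `U` universe KOs
independently per genome with probability `c_i`; since every KO falls into
(all, some, none) independently, a replicate is a single multinomial draw.
The test is one-sided (lower tail, depressed sharing = strain-level gene
content differences) with a +1 pseudo-count so p is never zero.

## Artificial genome reduction

A reference genome paired with a target completeness `c_t` (its partial
single-cell counterpart) is reduced to `n_t = round((c_t/c_g) * G)` genes
(ties round half to even): contigs are shuffled uniformly, whole contigs are
taken greedily while the cumulative gene count stays below `n_t`, and the
final contig contributes a contiguous window of exactly the remaining
count. "Completeness" is operationalised in gene counts, not base pairs
(the final step targets a number of genes); a bp-based mode could be added
but nothing downstream consumes it.

**Window choice.** The stated purpose of the random window is equal
inclusion probability for every gene regardless of its position on the
contig. A linear (non-wrapping) window cannot deliver that — contig-end
genes are covered by fewer windows, and on a 3x10-gene toy genome the
per-gene inclusion probability would range 0.39-0.61 around the nominal
0.5, which a χ² test over a few thousand seeds rejects decisively. The
default window is therefore **circular** (uniform start over all `m`
positions, wrapping past the contig end), which makes within-contig
inclusion exactly uniform and, for equal-size contigs, makes the whole
procedure exactly uniform; `wrap=False` restores the linear behaviour for
comparison. Windows never span two contigs, and gene order and contig
membership are preserved. For unequal contig sizes the shuffled greedy fill
leaves a small layout-dependent deviation across contigs; averaged over
random layouts (as in the synthetic generator) the marginal retention still
equals the completeness.

Replicates use one child generator each, spawned from the run seed, so they
are independent and individually reproducible.

**Bias assessment.** Each of R replicates (1,000 by default; scaled-down
runs in the tests use 200) reduces every pair, re-calls pathways, and
recomputes corrected proportions with `c_i = c_t`. The two-sided
Monte-Carlo p is `min(1, 2*min(n_le+1, n_ge+1)/(R+1))`, Benjamini-Hochberg
adjusted across pathways ("FDR" is not otherwise specified; BH is the
standard choice). A pathway is underestimated when `FC < 1` and `q < 0.05`,
overestimated when `FC > 1` and `q < 0.05`. A pathway absent from every
unreduced genome reports `FC = NaN` and `not_significant` rather than
dividing by zero. Note the resolution limit: at R replicates the smallest
attainable p is `2/(R+1)`, so after BH a single biased pathway among M
cannot clear `q < 0.05` unless R is large or several pathways share the
floor.

## Co-occurrence network and guilds

For each unordered pair of functions, significance of joint presence across
N genomes is the exact upper hypergeometric tail `P[X >= k]`, summed in log
space. The "E-value" multiplies p by the number of pairs tested
(Bonferroni-style expected false edges) — the exact multiplicity convention
of the originating network tool is not documented, so the factor is
configurable (`multiplicity="pairs"` or `"none"`) and recorded in the
network metadata. Edges are retained at `E < 0.1`. Functions with
degenerate marginals (0 or N) are tested and logged, never dropped.

Guild clustering reimplements the edge-clustering-coefficient agglomeration
idea: edges sorted by descending `ECC(u,v) = (z+1)/min(deg u - 1, deg v - 1)`
(z = shared neighbours; bridges to degree-1 nodes sort first), merged in
order with lexicographic tie-breaks, returning the partition of maximum
modularity along the merge sequence. The published tool's parameters are
not specified anywhere we could transcribe them from, so correctness is
defined behaviourally — planted guilds must be recovered (Rand index >=
0.9 at carrier fraction 0.4 vs background 0.05) — and a greedy-modularity
alternative is provided as a cross-check. Isolated nodes stay unassigned.

## Diversity statistics

* **Chao1**: classic `S_obs + F1^2/(2 F2)`; at `F2 = 0` the bias-corrected
  `S_obs + F1(F1-1)/2`. The branch rule is recorded here because "Chao1"
  alone does not pin it down.
* **Rarefaction**: subsampling without replacement, 100 randomizations by
  default, percentile (2.5/97.5) band — the interval estimator is the
  package's choice; the mean is validated against the closed-form
  hypergeometric expectation `sum_i 1 - C(T-n_i, d)/C(T, d)`.
* **Bray-Curtis** delegates to `scipy.spatial.distance.braycurtis` after
  union-aligning category indices.
* **PERMANOVA**: pseudo-F from among/within sums of squared distances with
  the usual degrees of freedom, p by uniform label permutation,
  `(1 + #{F_perm >= F_obs})/(perms + 1)`; 10,000 permutations by default.
  The statistic is cross-checked against scikit-bio's implementation in the
  tests; singleton groups are permitted (they contribute no within-group
  term).

## Genealogical sorting index

On a rooted tree, the uniting nodes `U` of a `k`-leaf group are the
internal nodes on the paths from each group leaf to the group MRCA
(inclusive). We compute

```
gs     = (k-1) / sum_{u in U} (children(u) - 1)
gs_min = (k-1) / (L-1)
gsi    = (gs - gs_min) / (1 - gs_min)
```

For any clade shape — polytomies included — a monophyletic group has
`sum(children-1) = k-1`, hence `gsi = 1`; a group whose uniting nodes span
every internal node attains the `L-1` maximum, hence `gsi = 0`. The
statistic is topology-only (branch lengths and child rotations are
irrelevant). The normalisation uses the all-internal-nodes closed form even
when that configuration is not attainable for a given `k` and shape; a
degenerate guard handles trees (e.g. stars) where the normalising range
collapses. The permutation null shuffles leaf labels with the group size
fixed, `p = (1 + #{gsi_perm >= gsi_obs})/(R+1)`, 10,000 permutations by
default. Unifurcations are suppressed on ingest so degree terms are well
defined; an independently coded path-census oracle verifies the statistic
exhaustively on small trees.

## Habitat keyword flags

Free-text metadata is ASCII-folded, lower-cased and matched on whole words
(substring matching would let "lake" fire on "flake"; precision is
preferred because misses surface visibly as "unclassified"). Raised flags
are mapped through an ordered combination table — first row whose flags are
all raised wins, so specific rows precede general ones. The bundled rule
set (8 flags, 12 combinations) is a fixture; the YAML format accepts a
verbatim transcription of a fuller ruleset without code changes.

## Synthetic communities

Defaults encode the study conditions the pipeline targets: two habitats,
mean completeness 0.387 with Beta dispersion 4 (so roughly three quarters
of genomes fall below 50% completeness and a small tail below 10%),
contamination exponential with mean 0.4% (capped below the 5% ingest
screen), 4-10 contigs of 12-30 genes, two planted guilds (an
organotroph-like and a lithotroph-like set of the fixture catalog's
pathways), 5% background carriage, 10% multi-copy genomes, 10% unannotated
genes, log-series genus abundances (p = 0.9), and half of the genomes drawn
from habitat-private genus pools so that water-column and sediment
communities differ taxonomically — mirroring the clear compositional
separation such habitats show. Guild carriers receive every gene their
member pathways' rules require (one alternative set, one symbol per step);
filler genes use per-genus synthetic KO pools disjoint from the catalog, so
planted truth and rule evaluation coincide exactly on complete genomes.

Capture shares the reduction's contiguous-window mechanism (i.i.d. dropout
available as `capture_mode="iid"`), so the generator and the bias
assessment rest on one model and cross-validate each other.

What the generator does **not** emulate: nucleotide sequences, assembly
artifacts, annotation error (KO assignments are exact), phylogenetic
correlation between gene content and genus labels, uneven pathway
prevalence between habitats beyond guild/habitat restrictions, and real
catalog overlap between pathway definitions (fixture symbol sets are
largely disjoint). Passing tests therefore demonstrate correctness of the
estimators and rules under their stated model, not robustness to annotation
noise.

## Problem sizes and numerics

The test suite and the acceptance script run at deliberately modest sizes
chosen as the package's own reproducibility envelope: 500-genome
communities for fidelity and recovery, 5,000 seeds for the
inclusion-uniformity census, 50 pairs x 200 replicates x 5 seeds for the
scaled bias run, 200 datasets x 199-999 permutations for null calibration.
Monte-Carlo p-values always carry the +1 pseudo-count. `round()` (banker's
rounding) fixes gene-count ties; hypergeometric tails are summed in log
space via `gammaln`/`logsumexp`; empty reductions, zero-survivor
corrections and degenerate marginals raise or log explicitly rather than
returning silent zeros.

## Known limitations

* The E-value multiplicity convention and the guild tool's exact algorithm
  are reconstructions pinned by behaviour, not by a reference
  implementation.
* The per-genome correction is unbiased only for single-copy functions;
  multi-gene rules inherit the nonlinearity bias that the reduction module
  quantifies but does not remove.
* Cross-contig inclusion uniformity in the reduction is exact only for
  equal-size contigs; unequal layouts retain a small deviation (uniform in
  expectation over random layouts).
* The bundled pathway catalog and habitat rules are fixtures sized for
  testing; both formats accept fuller curated tables verbatim.
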