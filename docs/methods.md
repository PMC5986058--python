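# Methods

## Problem and model

The package analyses a rectangular multiple alignment of a functionally
diverse protein superfamily, partitioned into functional families
(specificity groups). Per column it distinguishes superfamily-wide
conservation from family-specific conservation, under a simple
observation model: each column is a sample of residues, each residue
carrying a family label; gaps and the ambiguity symbols B/Z/X are missing
observations. No phylogeny is modelled — sequences are treated as
exchangeable within their family. That assumption matters: real families
are tree-correlated, so shared ancestry alone can make residues look
family-associated. The permutation null tests exchangeability of family
labels, not independence given a phylogeny, and detected FSPs on real data
should be read as "family-associated residues", with phylogenetic
confounding in mind.

## Column statistics

For column j with residue variable X and family variable Y over effective
(non-gap, non-ambiguous) observations:

* **Conservation** = frequency of the commonest residue; consensus ties
  are broken alphabetically so results are deterministic.
* **Family association** = plug-in mutual information
  I(X;Y) = Σ p(a,f) log2[p(a,f)/(p(a)p(f))] in bits, with normalization
  nmi = I/min(H(X),H(Y)) (0 when either entropy is 0). The plug-in
  estimator is biased upward on finite samples; the permutation null makes
  the inference bias-robust because observed and permuted statistics share
  the bias.
* **Significance**: B label permutations, each applied to all columns at
  once (one shuffle per iteration rather than per column), preserving
  inter-column dependence under the null at the cost of B shuffles total.
  p = (1 + #{b: I_b ≥ I_obs})/(B+1); permuted values within 1e-12 bits of
  the observed value count as ties so that mathematically equivalent
  contingency tables are not split by floating-point noise.
  z = (I_obs − mean_b)/sd_b (0 if sd_b = 0).
* **FDR**: Benjamini–Hochberg q-values across all non-masked columns
  (statsmodels implementation).

The statistic is reported in output provenance as "plug-in MI +
label-permutation null + BH FDR". It is this package's own choice; no
numerical equivalence with any web-server statistic is claimed.

### Choosing B

The smallest achievable p-value is 1/(B+1), so BH discovery of k true
columns among n tested requires roughly (B+1) ≥ n/(q·k). The default
B = 1000 supports q ≤ 0.05 down to k ≈ 6 true positives among n = 300
columns; B = 500 cannot yield any discovery at q ≤ 0.05 for n = 300 unless
k ≥ 12 columns tie at the floor. `ScanConfig` refuses B < 99 (resolution
coarser than q = 0.05 even for a single test).

## Classification rules

Per column, first match wins:

1. **masked** — gap+ambiguity fraction > `gap_mask_threshold` (default
   0.50). Family-correlated gaps are indel signal, not residue signal, and
   are deliberately not scored (a recorded limitation).
2. **conserved** — conservation ≥ `conserved_min_freq` (default 0.98, not
   literal invariance: a column can define a superfamily-wide property
   while a handful of sequences deviate).
3. **conserved_with_exceptions** — the overall consensus is the confident
   within-family consensus (within-family frequency ≥ 0.90) in at least
   n_families − `exception_max_families` families (default: all but one).
   Two refinements beyond the bare rule, both recorded design choices:
   the agreeing families must strictly outnumber the deviating ones
   (otherwise 2-family data would label every diagnostic column an
   exception pattern), and an empty deviating list collapses to
   **conserved** (an exception class that names no exception is a
   conservation call).
4. **fsp** — q ≤ `fdr_q` (default 0.05) and ≥ `fsp_min_distinct_consensi`
   (default 2) distinct family consensi and ≥ 2 families with within-family
   consensus frequency ≥ `fsp_min_within_family_consensus` (default 0.90).
5. **variable** — everything else.

Thresholds live in `ScanConfig`; all are echoed into provenance output.

## Sequence-set cleaning

Within each family, relative to its representative:

* **Outlier filter**: remove sequences scoring < `min_bits_per_column`
  (default 0.5 bits; BLOSUM62 half-bit scores averaged over mutually
  non-gap columns and divided by two; no gap penalties — the score is a
  per-aligned-column average on the induced pairwise alignment) or whose
  ungapped length differs from the representative's by strictly more than
  `max_length_diff` (default 20%; exactly 20% is kept). A per-family cap
  (default 1000) then keeps the first survivors in sweep order.
* **Redundancy filter**: greedy sweep in input order, representative
  first; a sequence is removed iff its identity with an already retained
  sequence is ≥ `identity_threshold` (default 0.95 — the boundary
  collapses). Identity = matches / mutually non-gap columns, with
  ambiguity symbols treated as missing on both sides of the ratio, which
  keeps self-identity at 1 and makes the filter insensitive to terminal
  gaps.

Outliers are removed before redundancy so that redundancy among discarded
outliers cannot influence the result. Both filters are deterministic,
idempotent, and report a machine-checkable reason per removal.

## Core-guided merge

Family sub-alignments are merged through a core alignment holding one
representative per family. Each sub column either carries its
representative's i-th residue — and maps onto the core column holding that
residue — or is an insertion relative to the representative and becomes a
family-private column in which all other families are gapped. Insert
blocks are left-anchored immediately after the core column of the
preceding representative residue (virtual column 0 for leading
insertions); same-anchor blocks from different families follow family
input order. Insertions of different families are never aligned to each
other: without structural information such columns are not comparable.
Consequences, verified by tests: within-family residue correspondences are
exactly those of the sub-alignment, representative correspondences are
exactly those of the core, and the merged width is core width plus total
insert width.

## Specificity clustering

When no annotation is supplied, candidate partitions are cut from an
average-linkage dendrogram on distance 1 − identity. For each k in the
scanned range, groups smaller than `min_group_size` (default 2 — a
singleton cannot exhibit conservation) are absorbed into the group at
minimal mean distance, and the partition is scored by

* W(k): mean over groups and non-masked columns of the within-group
  top-residue frequency,
* B(k): mean over non-masked columns of the fraction of group pairs whose
  consensus residues agree (0 when fewer than two groups have data),
* Q(k) = W(k) − B(k), maximized with ties to smaller k.

W rewards within-group conservation and B penalizes partitions whose
groups agree with each other — a concrete, deterministic instantiation of
"conserved within, variable between". The trace of (k, W, B, Q) is
returned and written, and the objective name is recorded in provenance.
Supplying an annotation bypasses this stage entirely.

## Synthetic data

The planted-column generator emulates the statistical structure the
scanner targets: conserved columns (planted residue, per-cell deviation
rate ε_c), exception columns (one family carries its own residue,
planted noise-free — deviation rates are a property of the conserved and
FSP plantings only), FSP columns (per-family residues, deviation rate
ε_f), i.i.d. background (uniform over the 20 residues by default — the
maximum-entropy, hardest null for false conservation), and per-cell gaps.
Planted columns are gap-protected by default so recovery tests isolate the
statistic from gap masking; an unprotected mode exercises masking. A
second generator produces merge fixtures with planted insertions, and a
third produces family-structured alignments whose within/between-family
identities are set analytically (retention probabilities solved from the
requested identities under the uniform background). What the generators do
**not** model: phylogenetic correlation, indel evolution, realistic
amino-acid composition, alignment errors. Passing recovery tests therefore
demonstrate correctness of the statistics under the stated model, not
performance on real superfamilies.

## Problem sizes and reproducibility checks

`scripts/acceptance.py` regenerates, from scratch at run time: planted
recovery on 5 families × 50 sequences × 300 columns (10 FSP columns at
ε_f = 0.05, 5 conserved at ε_c = 0.01, 1 exception, 2% protected gaps,
B = 1000); null calibration on 20 all-background replicates of the same
shape (B = 500); the MI-vs-brute-force maximum error over 1000 random
small profiles; merge fidelity over 200 random fixtures; clustering
recovery over 20 replicates of 3 × 20 × 120 at ~0.85/~0.25 identity; and a
byte-identity check of a repeated pipeline run. These sizes keep the whole
script within a few minutes on one CPU while leaving the binomial bands of
the stochastic checks tight.

## Numerical and degenerate-input choices

* Alignment columns are 1-based everywhere; reference numbering offsets
  are configurable per family so outputs can match PDB numbering.
* Residues are upper-cased on read; `.` is accepted as a gap alias.
* `bits_per_column` with zero shared non-gap columns returns −∞, which
  fails any finite threshold.
* Identity with zero shared columns is 0.
* A column with no effective observations has undefined conservation and
  is always masked.
* All RNG use goes through `numpy.random.default_rng` with explicit seeds;
  the permutation stream is independent of the data-generation stream.
* Floats in TSV output are formatted with `%.6g`, making repeated runs
  byte-identical.

## Known limitations

* No phylogenetic correction (tree-correlated families inflate MI).
* Gap patterns are masked, not modelled; family-diagnostic indels are
  invisible to the scanner.
* The clustering objective is greedy over a single average-linkage
  hierarchy; it is not claimed optimal over all partitions, nor equivalent
  to any published server's clustering.
* Cross-family insertions are kept unaligned by design; merged alignments
  are therefore wider than a structure-aware merge could make them.
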