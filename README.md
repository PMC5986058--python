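# fspscan

Comparative analysis of functionally diverse protein superfamilies from a
multiple sequence alignment: find the positions that hold the superfamily
together, and the positions that tell its families apart.

Enzyme superfamilies such as the fold type I PLP-dependent enzymes (the
aspartate aminotransferase superfamily) implement many different reactions
on one structural scaffold. Two kinds of alignment columns carry the
signal a protein engineer cares about:

* **conserved positions** — occupied by (nearly) one amino acid type across
  the whole superfamily, typically the shared catalytic machinery; a single
  family may deviate (*conserved with exceptions*);
* **family-specific positions (FSPs)** — conserved *within* each functional
  family but occupied by *different* residues in different families;
  candidate determinants of substrate and reaction specificity, and natural
  hotspots for mutagenesis.

`fspscan` takes an aligned superfamily (or per-family sub-alignments plus a
core alignment of one representative per family), an assignment of
sequences to functional families (given, or inferred by clustering), and
classifies every alignment column, reporting results in the residue
numbering of each family's representative (e.g. `K199`).

## Method

For column *j* let `X` be the residue (gaps and `B/Z/X` excluded) and `Y`
the family label. The pipeline computes:

* conservation `max_a f(a)` — the frequency of the commonest residue;
* family association as plug-in mutual information
  `I(X;Y) = Σ_{a,f} p(a,f) log2 [ p(a,f) / (p(a) p(f)) ]` (bits), plus the
  normalization `I / min(H(X), H(Y))`;
* a one-sided permutation p-value: family labels are permuted across
  sequences B times (one shared permutation per iteration for all columns),
  `p = (1 + #{b : I_b ≥ I_obs}) / (B + 1)`, with a z-score against the
  permutation distribution;
* Benjamini–Hochberg q-values across all non-masked columns.

A column is then *masked* (gap fraction > 0.5), *conserved* (consensus
frequency ≥ 0.98), *conserved with exceptions* (all but ≤ 1 family
confidently share the consensus), an *FSP* (q ≤ 0.05, ≥ 2 distinct family
consensi, ≥ 2 families conserved at ≥ 0.90 within themselves), or
*variable*.

Supporting stages mirror the standard superfamily-construction protocol:
per-family redundancy filtering (collapse pairs at ≥ 95% identity),
outlier filtering (< 0.5 bits/column against the family representative
under BLOSUM62, or ungapped length differing by more than 20%), merging of
family sub-alignments through the core alignment of representatives, and —
when no annotation exists — specificity-group clustering that maximizes
within-group conservation minus between-group consensus agreement
(`Q = W − B`) over average-linkage partitions.

## Worked example

Simulate a 3-family alignment (10 sequences per family, 40 columns) with
one planted conserved column, one exception column and two planted FSPs,
then scan it:

```bash
cat > synth.yaml << 'YAML'
n_families: 3
seqs_per_family: 10
n_columns: 40
conserved_columns: [[5, K, 0.01]]
exception_columns: [[9, R, fam3, V]]
fsp_columns:
  - [12, {fam1: H, fam2: F, fam3: S}, 0.05]
  - [20, {fam1: D, fam2: T, fam3: N}, 0.05]
gap_rate: 0.02
seed: 4
YAML
fspscan simulate --config synth.yaml --out-prefix sim
fspscan scan --alignment sim.fasta --families sim.families.tsv --out positions.tsv
```

The scan prints `2 conserved, 2 FSP columns` and the non-variable rows of
`positions.tsv` read (first ten fields):

```
column  class                      consensus  conservation  mi        nmi  p            q        z        exception_families
5       conserved                  K          1             0         0    1            1        0        -
9       conserved_with_exceptions  R          0.666667      0.918296  1    0.000999001  0.01332  16.8533  fam3
12      fsp                        H          0.333333      1.58496   1    0.000999001  0.01332  18.3257  -
20      fsp                        N          0.333333      1.58496   1    0.000999001  0.01332  17.3047  -
```

Column 5 is invariant lysine (conservation 1, MI 0). Column 9 is arginine
in two families but valine throughout `fam3`: conserved with exceptions,
with the deviating family named. Columns 12 and 20 reach the maximal MI
for three equal balanced families (`log2 3 ≈ 1.585` bits), the smallest
achievable permutation p-value at B = 1000, and survive FDR control: FSPs.
The per-family reference columns (not shown) give each verdict in
representative numbering, `N/A` where that representative is gapped.

`fspscan run --config pipeline.yaml --out-dir out` drives the full
pipeline (filter → merge → cluster-or-annotate → scan → report) from one
YAML file; `fspscan merge`, `filter`, `cluster` and `report` expose the
individual stages.

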