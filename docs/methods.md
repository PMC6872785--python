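# Methods

## Background and model

Serine is encoded by two codon sets — TCN (S′) and AGY (S″) — whose
minimum Hamming distance is 2, so no single point mutation converts one
set into the other. Each set therefore sits in its own substitution
neighbourhood: a single transition from AGY reaches glycine and asparagine
(together the **GS″N** group), while a single first-position change from
TCN reaches proline and alanine (**S′PA**). Threonine is reachable from
both sets and belongs to neither group. The package quantifies how these
two groups distribute over protein positions under purifying versus
diversifying selection, at four evolutionary scales: deep vertebrate-style
codon alignments, a hypervariable antigen (gp120-style region masks),
B-cell-receptor repertoires, and population exome variants at
phosphorylation sites. All computations run on synthetic inputs from the
package's own seeded generators; nothing is downloaded.

Split-alphabet conventions: ASCII `S1`/`S2` (and `L1`/`L2` for CTN/TTR,
`R1`/`R2` for CGN/AGR) are used everywhere; Unicode primes are accepted on
input. The arginine split is not named in a way that fixes which set is
"primed"; we assign `R1 = CGN` so that the 4-codon, third-position-
degenerate set is always the primed one, mirroring serine and leucine.

## Split substitution matrices

`count_pairs` accumulates unordered symbol pairs per codon column over
alignment blocks, reading codons so serine columns can be classified by
codon set. Derived quantities follow the classic blocks-matrix
construction: pair frequencies `q_ij`, backgrounds
`p_i = q_ii + Σ_{j≠i} q_ij / 2`, expectations `e_ii = p_i²`,
`e_ij = 2 p_i p_j`, and half-bit integer scores
`s_ij = round(2·log₂(q_ij / e_ij))`, rounding halves away from zero.
Choices where the construction is under-specified:

* **Clustering** — optional Henikoff-style single-linkage identity
  clustering with weights 1/cluster-size and within-cluster pairs skipped;
  default off (the appropriate threshold for genome-scale input is not
  knowable from the construction alone, so it is a user parameter).
* **Zero cells** — default pseudocount 0 with a `−99` sentinel score;
  a Laplace pseudocount is available and removes the sentinel.
* **Gaps and stops** — a gapped or stop codon removes that sequence from
  that column only; columns left with depth < 2 contribute nothing.

Collapsing the split rows/columns of the pair-count matrix reproduces the
unsplit counts exactly (cross-set pairs collapse onto the diagonal once);
this identity and a brute-force pair-enumeration oracle on small blocks
are the module's primary correctness checks.

## Diversity and the meaningful set

Per column the order-1 Hill number `D = exp(−Σ p_i ln p_i)` is computed
over the 20 unsplit amino acids (splits affect downstream classification,
never diversity). The meaningful set holds the `n` most abundant amino
acids where `n = max(1, round(D))` with halves rounded away from zero;
ties at rank `n` are all included, which keeps the call deterministic and
order-independent. A position is *serine-meaningful* when S is in the set.
Quartile partitions of diversity exclude Tukey 1.5×IQR outliers first and
use linear-interpolation quartiles; the extreme groups are strictly above
Q3 / below Q1. The rounding rule, tie policy, outlier rule and quartile
estimator are package choices made once where the procedure is otherwise
under-determined; all are deterministic and documented here.

## Region enrichment

GS″N membership: amino acid G or N, or serine encoded AGY; S′PA: P or A,
or serine encoded TCN; the groups are disjoint by construction. The
per-position *fraction* of sequences matching a group is the sample unit
for all rank statistics (no sequence-level resampling). Analysis is
restricted to serine-meaningful positions before any test, identically for
both groups. Tails: two-tailed Mann-Whitney for the diversity-quartile
contrast, one-tailed for the hotspot contrast (GS″N tested hotspot >
other, S′PA hotspot < other), matching the directional hypotheses for
diversifying versus conserved regions. The member sets of
`SubstitutionGroup` are configurable, so variants of the second group
(e.g. an S′PT reading that swaps alanine for threonine) can be tested;
S′PA is the default because threonine is reachable from both serine sets
and belongs to neither neighbourhood. Hotspot labels are always an input
mask — there is no de novo hotspot detection.

## Repertoire pipeline

Inputs are pre-aligned, IMGT-numbered V-region nucleotide sequences paired
with their germline (AIRR-rearrangement-like TSV). Filters, in order:
sequences with a mutated-nucleotide fraction strictly above 0.30 are
dropped (ambiguous germline assignment), then individuals with fewer than
3 surviving sequences. Clones are records sharing (V gene, J gene, CDR3
length) within an individual; a mutational event is a distinct (position,
germline codon, observed codon) triple counted once per clone regardless
of member multiplicity. Region bounds (1-based IMGT): FWR1 1–24, CDR1
25–40, FWR2 41–53, CDR2 56–65, FWR3 66–104, CDR3 from 105; analysis stops
at amino-acid position 106 and is further restricted to positions 25–30,
35–59, 63–72, 74–106 covered by ≥ 30 sequences.

Serine-meaningfulness is called per individual from the germline
amino-acid profile across clones. The germline contrast takes, per
meaningful position, the fraction of clones whose germline codon matches
the group, then the median over CDR and over FWR positions; the
per-individual statistic is the CDR − FWR difference. The somatic contrast
uses positions carrying at least one event and scores
GS″N / (GS″N + S′PA) among the deduplicated substituted codons; an
individual with no usable substitutions is excluded from that statistic.
Across individuals a Wilcoxon signed-rank test is applied to the
differences, with the exact null distribution forced for cohorts of ≤ 25
(ties in the differences would otherwise silently switch scipy to the
normal approximation).

A note on the null: with equal serine codon-set bias in both regions the
*sign* of the median difference is close to, but not exactly, a fair coin
(measured ≈ 0.55 positive among non-zero differences over 600 simulated
cohorts). The residual skew comes from comparing sample medians of a
skewed, discrete fraction distribution over regions of unequal size
(~21 analyzed CDR vs ~53 FWR positions); it is a property of the
median-difference statistic itself, not of the implementation. Zero
differences (frequent at small clone counts) are reported but excluded
from the success proportion.

## Neutral model and phosphosite network

From mapped SNVs (major → minor allele, high-quality, inside a CDS,
stop codons excluded on both sides):

* **C**, 61×61: events / occurrences of the source codon in the CDS set,
  diagonal completed so rows sum to 1;
* **M**, 4×4: same normalisation restricted to third positions of the
  fourfold-degenerate families of V, P, T, A and G. The third-position
  quartets inside the six-codon families (CTN, TCN, CGN) are excluded by
  default — the five-family set keeps the neutral sites maximally
  unambiguous — but can be included;
* **E**, 61×61: `E[c→c'] = M[c₁→c₁']·M[c₂→c₂']·M[c₃→c₃']` over sense
  codons, stop-target mass dropped, diagonal recompleted. Dropping rather
  than renormalising keeps E on the same convention as C.

The phosphosite network aggregates sources into S′, S″, T and Y codon
sets over the analysed sites, restricts targets to single-point-mutation
neighbours, and scores each (source set → target amino acid) edge as
`r = log₁₀(observed/expected)` with observed and expected both normalised
by the source set's codon occurrences among the sites
(occurrence-weighted, not uniform over member codons). `|r| ≤ 1` is
neutral, `r > 1` enriched, `r < −1` depleted; a source set with zero
observed events scores −∞ (reported explicitly, never silently zero).
`fold_difference(a, b, target) = (obs/exp)_a ÷ (obs/exp)_b`; a planted
suppression of the S′→T edges by 1/32 is recovered as
`fold_difference(S″, S′, T) ≈ 32`. Exact scale invariance of `r` under
multiplying all SNV counts holds up to the staying-probability diagonal
factors of E, which shift by order of the per-site mutation rate.

## Synthetic generators

Every generator is a pure function of its spec, seed included; random
streams are forked per position/individual with `SeedSequence.spawn`, so
reruns are byte-identical and partial regeneration is stable.

* `simulate_msa` — per-column amino-acid frequencies from a symmetric
  Dirichlet over a regime pool (concentration ≈ 0.1–0.5 for conserved,
  ≥ 2 for diverse columns); residues i.i.d. per sequence; serine encoded
  AGY with probability β, codons uniform within a set.
* `simulate_repertoire` — defaults of 20 individuals × 30 clones × 3
  members echo a small human cohort at desk scale; germline residues from
  a serine-enriched pool (serine weight 0.25, so serine is meaningful at
  most positions), β per region, somatic single-nucleotide codon changes
  at rate 0.02/codon/member, optionally steered toward the region's
  preferred group.
* `simulate_exome` — one independent draw from the true 4×4 matrix M* per
  CDS nucleotide (a diagonal draw is no variant), which makes the neutral-
  model estimator unbiased for M*; per-edge selection factors thin drawn
  codon changes; phosphosites placed on S/T/Y codons. The default M* has
  0.06 off-diagonal mass per base with transitions twice transversions — a
  deliberately polymorphism-dense regime so moderate CDS sizes populate
  the matrices. `ExomeSimSpec.for_events` sizes the CDS so the expected
  SNV count hits a target.

What the generators do *not* emulate: phylogenetic correlation between
sequences (columns are i.i.d. given their frequencies), indels,
sequencing error, germline allele diversity within a V gene, linkage
between nearby SNVs, and realistic codon-usage skew unless supplied.
Passing tests therefore demonstrate correctness of the statistics and
recoverability of planted codon-level structure, not performance on real
data with those additional correlations.

## Problem sizes and numerical choices

The test suite and acceptance script run the stochastic checks at fixed,
seeded sizes chosen as the package's own desk-scale study conditions:
neutral-model recovery at ~10⁵ SNVs (measured max absolute entry error
≈ 0.002, against a 0.02 band), planted-selection recovery at ~2×10⁵ SNVs
(≥ 10⁴ of them at phosphosites; fold difference 27–42 across seeds against
a 32 ± ×1.5 band), enrichment calibration over 1000 label permutations,
and the repertoire null over 200 cohorts of 5 individuals. Degenerate
inputs raise explicit errors rather than returning silent zeros: empty
codon sets, all-gap columns, all-zero count vectors, constant correlation
input, empty test groups, cohorts with all-zero differences, and rows of C
whose events exceed their occurrences.

## Known limitations

* Blocks are whatever alignments the caller provides; there is no
  conservation-based block detection, and inputs must be pre-aligned and
  in frame (repertoire inputs pre-aligned and IMGT-numbered).
* The unsplit 20-letter matrix built here is not a reproduction of the
  original published BLOSUM62 (different blocks, unknown clustering).
* Only diversity order 1 is implemented.
* The repertoire median-difference null has the small size-asymmetry skew
  described above; cohort conclusions rest on the signed-rank test, which
  is exact, not on the raw success proportion.
* VCF input is read in CDS coordinates (CHROM = CDS id); genome-to-CDS
  mapping is out of scope.
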