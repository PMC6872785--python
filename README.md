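# sercodon

Analysis of serine's two disjoint codon sets and the distinct substitution
patterns they carry at conserved versus diversifying protein positions.

## The problem

Serine is the only amino acid encoded by two codon sets that cannot be
interconverted by a single point mutation: **S′ = TCN** (TCT, TCC, TCA, TCG)
and **S″ = AGY** (AGT, AGC), separated by a minimum of two nucleotide
changes. Each set therefore has its own single-mutation neighbourhood:

* **GS″N** — glycine, AGY-serine and asparagine (transition neighbours of
  S″), amino acids that favour β-turns and are expected at positions under
  diversifying selection;
* **S′PA** — TCN-serine, proline and alanine (first-position mutation
  neighbours of S′), expected at positions under purifying selection.

`sercodon` implements the full analysis chain that tests this hypothesis,
for anyone studying codon-level selection in deep vertebrate alignments,
rapidly evolving viral antigens, B-cell-receptor repertoires or population
exome variants — with seeded synthetic generators so every stage runs
without any external download.

## What is implemented

| module | contents |
|---|---|
| `genetic_code` | the standard code, the S′/S″ (and L′/L″, R′/R″) splits, single-mutation neighbourhoods, codon-set Hamming distances |
| `split_blosum` | BLOSUM-style half-bit log-odds matrices over the split alphabet: `s_ij = round(2·log₂(q_ij / e_ij))`, with Henikoff-style clustering, pseudocounts, and split-vs-unsplit comparison |
| `diversity` | per-column order-1 Hill diversity `D = exp(−Σ p_i ln p_i)`, the meaningful-amino-acid set (the `n = round(D)` most abundant residues) and the serine-meaningful predicate |
| `enrichment` | per-position GS″N / S′PA fractions, Spearman correlation with diversity, diversity-quartile and hotspot-vs-rest Mann-Whitney tests |
| `repertoire` | BCR heavy-chain pipeline: 30%-mutation and 3-sequence filters, clones by (V, J, CDR3 length), IMGT CDR/FWR contrasts, cross-individual Wilcoxon signed-rank test |
| `phospho` | observed 61×61 codon substitution matrix from SNVs, 4×4 neutral model from fourfold-degenerate third positions, expected matrix under position independence, phosphosite substitution network with `r = log₁₀(obs/exp)` scores |
| `simulate` | seeded generators for codon alignments, clonal repertoires and exome SNV tables with planted effects |
| `io` / `cli` | FASTA/TSV/VCF/YAML readers and writers, `sercodon` umbrella command |

## Worked example

Simulate a codon alignment whose serines are AGY-biased at diverse
positions, then test GS″N enrichment against diversity:

```python
from sercodon import (MsaSimSpec, RegimeSpec, simulate_msa, analyze_alignment)

spec = MsaSimSpec(n_sequences=100, regimes=[
    RegimeSpec("conserved", 100, pool="SPATVLID", concentration=0.3, beta=0.0),
    RegimeSpec("diverse",   100, pool="SGNATVLID", concentration=4.0, beta=1.0)],
    seed=1)
result = analyze_alignment(simulate_msa(spec))
print(len(result.serine_positions))
print(result.quartile["GS2N"].medians, result.quartile["GS2N"].p_value)
print(result.spearman["GS2N"])
```

prints

```
137
{'high': 0.32, 'low': 0.0} 3.61509513135282e-14
(0.7041033628834477, 8.186393157618318e-22)
```

i.e. serine is a meaningful amino acid at 137 of 200 positions; the median
GS″N fraction in the top diversity quartile is 0.32 against 0.00 in the
bottom quartile (two-tailed Mann-Whitney p ≈ 4·10⁻¹⁴), and the GS″N
fraction correlates positively with per-position diversity (Spearman
ρ = 0.70) — recovering the planted codon-set structure.

The same stages are available from a shell:

```bash
sercodon simulate msa --seed 1 --out sim
sercodon build-blosum --alignment sim/alignment.fasta --out blosum
sercodon region-enrich --alignment sim/alignment.fasta --out enrich
```

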