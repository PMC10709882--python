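# Methods

This note records the models, conventions and numerical choices behind
`codonselect`, and what the synthetic-data experiments do and do not
demonstrate about real transcriptome data.

## CDS admission

A sequence is admitted when it (i) exceeds 300 bp (strictly — 300 bp
exactly is rejected), (ii) starts with ATG, (iii) ends with TGA, TAG or
TAA, (iv) has length divisible by 3, (v) contains no in-frame internal
stop, and (vi) contains no ambiguous base. Rules (iv)–(vi) are stricter
than the minimal length/start/stop screen often reported for this kind
of study; they are required for unambiguous codon counting, and a
rejected record carries the first failing rule in the order above.
Input is uppercased, U is mapped to T, and IUPAC ambiguity codes other
than N are mapped to N.

## Codon-usage statistics

All statistics are computed from codon count tables (terminal stop
excluded). Stops never enter any statistic; ATG and TGG, having no
synonymous alternative, are excluded from CAI, CBI, the third-position
"s" compositions and optimal-codon candidacy, and report RSCU = 1 when
observed. Undefined values are NaN throughout and only rounded for
display (percentages half-up to 2 decimals).

**ENC.** Wright's estimator with per-family homozygosity
F̂ = (nΣp²−1)/(n−1) for families with n ≥ 2 counts, averaged within the
2-, 3-, 4- and 6-fold degeneracy classes (Leu/Ser/Arg are treated as
6-fold here). Families with F̂ = 0 (possible at small n) are dropped
from their class mean. If the 3-fold class (Ile alone) is missing,
1/F̄₃ is imputed as the mean of 1/F̄₂ and 1/F̄₄; if any other class is
missing the statistic is undefined. The value is capped at 61.

**CAI.** Relative adaptiveness w is built from a reference set by
pooling counts; unobserved codons of observed families get a floor of
w = 0.01 (avoids ln 0, standard practice), wholly unobserved families
are neutral (w = 1). Because no organism-specific reference set is
assumed, per-gene CAI is bootstrapped in two deterministic passes:
rank against corpus-wide w, rebuild w from the provisional top 10%,
re-rank. Ties always break by gene id.

**PR2.** Restricted to the eight fourfold codon boxes (Ala, Gly, Pro,
Thr, Val and the fourfold halves of Leu CTN, Ser TCN, Arg CGN), since
parity arguments apply only where all four third-position bases are
synonymous.

## Optimal codons

The top and bottom ceil(0.10·N) genes by CAI proxy the highly/lowly
expressed sets (at least 20 usable genes by default). A codon is
optimal when RSCU in the high set ≥ 1.0 and ΔRSCU ≥ 0.08, both
inclusive. The universal set defaults to the strict intersection across
species; `min_species` relaxes it to "optimal in at least k species".

**Known limitation — the extreme-CAI null.** Ranking genes by CAI and
contrasting the tails is self-selecting: even in a corpus with *no*
expression-linked bias, the top-CAI genes are by construction enriched
for whichever codon happened to receive the largest weight in each
family, which manufactures ΔRSCU of roughly 0.1–0.25 for one codon per
family. This artifact does not shrink with corpus size. Per-species
optimal-codon calls from CAI partitions therefore always contain noise
calls; what is interpretable is (a) codons called against a genuine
expression contrast, and (b) the cross-species intersection, in which
species-independent noise cancels. The null-model experiments
accordingly contrast the generator's true expression classes, and the
recovery experiments require the multi-species universal set — not any
single species' call list — to equal the planted truth.

## Orthology

One-to-one pairs are found by reciprocal best hit over global
(Needleman–Wunsch, affine-gap) protein alignments, BLOSUM62 with gap
open 10 and extension 0.5 (a length-k gap costs open + (k−1)·extend).
Best hits use a score-only pass; ties break toward the
lexicographically smaller gene id. A mutually-best pair is kept when it
clears three floors, all configurable: identity ≥ 0.3 over aligned
residue pairs, coverage ≥ 0.5 of the longer protein, and alignment
score ≥ 0.25 per residue of the shorter protein. The per-residue score
floor is the desk-scale analogue of an E-value cutoff: optimal gapped
alignments of unrelated same-composition proteins sit near 30% identity
(the twilight zone) but score close to zero per residue, whereas
genuinely homologous pairs score an order of magnitude higher, so the
identity floor alone does not separate long random matches and the
score floor does. The aligned protein columns are threaded back onto
the source CDS; columns with a gap or an N on either side are dropped,
and pairs with fewer than 30 gap-free codons are discarded (variance
control for Ka/Ks).

This RBH stand-in reproduces the one-to-one output of graph-based
orthogroup inference for the two-species case but does not model
paralog clustering or many-to-many groups; it is a deliberate fidelity
deviation suitable for desk-scale corpora.

## Ka/Ks

**NG86.** Synonymous site fractions per codon position are taken over
non-stop single-base mutants; difference counts average over all
minimal mutational pathways that avoid stop codons (equal weights);
Jukes–Cantor correction d = −(3/4)ln(1−(4/3)p) applied to ps = Sd/S and
pn = Nd/N, undefined at p ≥ 0.75. S + N = 3·(codons) exactly.

**YN00.** The approximate method of Yang and Nielsen (2000),
re-derived rather than ported: κ is estimated from fourfold-degenerate
and nondegenerate site classes via K80 on each class, combined by site
weight (κ = 2A/B; fallback 1 when the data cannot support an estimate);
codon frequencies are F3x4 (position-specific base frequencies over the
pair, normalised over sense codons) or uniform (for oracle comparisons);
sites are counted per codon with mutation-rate weights κ^ts·π(target);
differences are pathway-averaged with weights κ^ts·π(target)·ω^nonsyn;
dS and dN are K80-corrected from their transition/transversion splits;
and ω = dN/dS is iterated to a fixed point (tolerance 1e-6, at most 100
iterations; non-convergence is flagged).

**Classification.** Ka/Ks < 0.5 purifying, 0.5–1 weak positive, > 1
strong positive; boundary values (exactly 0.5 or 1.0) fall to the lower
class (conservative). Pairs with Ks ≤ 1e-6 (unstable ratio) or Ks > 3
(saturation) are left unclassified; both bounds are configuration. The
commonality table records, per focal-species gene, the set of species
pairings in which its ratio exceeds 1, grouped into Venn cells.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not *Gleditsia* realism:

- **Biased corpus**: 500 genes per pseudo-species by default, lengths
  uniform on 101–400 codons (so every gene clears the 300-bp rule),
  amino acids uniform over the 18 degenerate families, ATG start and a
  random stop appended. Expression is a latent binary class
  (P(high) = 0.5): high-expression genes draw synonymous codons with
  probability mass b moved onto the family's preferred codons
  (default planted set: AGA+AGG for Arg, CCA for Pro, mirroring the
  universal codons reported for the genus), low-expression genes draw
  uniformly. Defaults are a desk-scale stand-in for corpora of tens of
  thousands of CDS per species.
- **Ortholog divergence**: a uniform-random sense-codon ancestor
  evolves along two lineages under a GY-style continuous-time codon
  model (transition rate ∝ κ, nonsynonymous rate ∝ ω, stops forbidden),
  simulated exactly event by event. Rates are normalised so the mean
  total rate over the 61 sense codons is 1 per codon, making t the
  expected number of substitutions per codon per lineage.
- **Two-species bundles** add unrelated random decoy genes per species
  and support a per-pair ω list (e.g. a {0.2, 1.5} grid).

Not modelled: realistic gene-length/GC distributions, indels (codon
alignments are generated gap-free; gap handling is exercised on
hand-built alignment cases), rate heterogeneity along the sequence, and
expression as a quantitative value. Passing recovery tests therefore
demonstrates correctness of the estimators and the pipeline plumbing
under the stated generative model — not robustness to assembly noise,
alignment error or compositional heterogeneity in real transcriptomes.

## Problem sizes and determinism

The test and acceptance experiments use: 50 random tables for formula
oracles; the full 61×61 sense-codon grid for NG86 counting; 20 seeds ×
6 pseudo-species × 500 genes for optimal-codon recovery; 50 replicate
pairs of 500 codons per (ω, κ) grid point; and 50 orthologs + 10 decoys
per species end to end. These sizes give comfortable statistical margins
for every claimed window while keeping a full run in the minutes range
on one CPU. All randomness flows from explicit integer seeds
(numpy `default_rng`); identical configuration yields byte-identical
outputs, and the pipeline writes every threshold and seed to
`run_log.json` so any reported number is reproducible from the log.
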