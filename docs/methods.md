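# Methods

## Model

A mature miRNA recognises a target principally through its seed,
nucleotides 2–8 from the 5′ end. `mirsnp` treats target recognition as a
binary, sequence-only event: a window is bound by a miRNA iff it contains
a canonical seed-match site — a literal Watson–Crick complement of the
seed on the mRNA sense strand. The four canonical site classes are

| type    | pattern on the mRNA (5′→3′)      | length |
|---------|----------------------------------|--------|
| 6mer    | revcomp(miRNA 2–7)               | 6      |
| 7mer-A1 | revcomp(miRNA 2–7) + `A`         | 7      |
| 7mer-m8 | revcomp(miRNA 2–8)               | 7      |
| 8mer-1a | revcomp(miRNA 2–8) + `A`         | 8      |

When site classes nest at one locus (one occurrence of the seed 2–7 core),
only the highest-priority *counted* class is reported
(8mer-1a > 7mer-m8 > 7mer-A1 > 6mer). Counted classes default to
{8mer-1a, 7mer-m8, 7mer-A1}; 6mer sites are marginal and are opt-in via
configuration. No G:U wobble, no 3′-supplementary pairing, no context or
conservation scoring, no binding-energy model: presence/absence of a
canonical site is the entire model. `N` positions never match.

For a biallelic coding SNP the two alleles are embedded at the centre of
31-nt windows (15-nt flanks each side — long enough that every site class
overlapping the variant base lies fully inside the window; flanks truncated
by a CDS boundary are used as-is and flagged). The SNP **changes miRNA
regulation** when the *sets of binding miRNAs* differ between the two
windows. Counting at the miRNA level, not the site level, means a variant
that merely relocates a site of a miRNA bound under both alleles is not a
change; variants altering only binding affinity are out of scope by
construction. Because the windows differ at a single base, every
differential site overlaps the variant position — this locality is asserted
as a property test rather than assumed.

## Statistics

All enrichments share one 2×2 layout: rows changed/unchanged, columns
annotated/not, sample odds ratio `ad/bc` (+∞ when `bc = 0 < ad`, undefined
when both products vanish; no Haldane–Anscombe correction), and Fisher's
exact test. Two-sided Fisher p-values use the probability-mass convention
(sum of all fixed-margin table probabilities not exceeding the observed
one), matching R's `fisher.test`; one-sided alternatives are exposed
because screening claims of the form "changed SNPs prefer annotation X"
are directional, and published analyses of this design mix the two
conventions. A table with a zero margin is degenerate: p = 1, flagged.

* **Selection screen.** |iHS| ≥ 2.5 (inclusive) flags strong recent
  positive selection. SNPs without an iHS value are excluded from the
  universe, not imputed as unselected. Distribution-level shifts are
  tested by Wilcoxon rank-sum: exact null when both samples have ≤ 50
  observations and no ties, otherwise the normal approximation with
  continuity and tie correction.
* **Permutation null.** For the overlap of the changed set with an
  annotated set, each of `n_perm` permutations (default 10,000) draws
  |changed| ids uniformly without replacement from the universe — no
  matching on allele frequency or gene length. The null is therefore
  Hypergeometric(N, K, n), which the tests verify by expectation and
  goodness of fit. The empirical p is +1-corrected and one-sided upper-tail
  by default (the claim is directional); two-sided is available.
* **Expression association.** Per SNP–gene pair, Spearman rank correlation
  of dosage (0/1/2, missing dropped pairwise) against expression; average
  ranks for ties; two-sided p via the t-approximation for n ≥ 10 and exact
  permutation enumeration below that. Monomorphic genotypes are flagged
  untestable and excluded from gene-level tallies. At the gene level a
  gene is significant when *any* of its SNP associations has p ≤ α
  (α = 0.05); genes are partitioned by hosting ≥ 1 changing SNP. This
  any-SNP / nominal-α aggregation is deliberately anti-conservative and is
  a screening device, not eQTL discovery. The SNP→gene relation is an
  explicit input, sidestepping both multi-SNP gene pairing and expression
  normalisation choices.
* **No multiple-testing correction** is applied anywhere; every p-value is
  nominal and should be read as such.

## Synthetic data

The generator produces inputs with exactly the structure the statistics
assume, each stage a pure function of (config, seed):

* **Catalog** — `n_mirnas` random 22-nt mature sequences with unique names
  and unique seed heptamers (collisions redrawn; two identical seeds would
  be indistinguishable to a seed-level scanner). Default 100 miRNAs: large
  enough that incidental background sites occur, small enough that planted
  constructions converge quickly; the human catalog is ~20× larger, which
  changes the background site density but nothing structural.
* **SNPs** — each SNP is independently "changed" with probability
  `change_rate_target` (default 0.459, the genome-wide changed fraction
  this regime emulates). Changed SNPs are *constructed*: a counted site
  pattern is embedded so it overlaps the central base, and the alternate
  allele replaces that base; unchanged SNPs are random windows. In both
  arms the scanner itself verifies the intended binding relation in-loop
  (the substitution could leave a lower-priority site or create one for
  another miRNA), so truth labels are exact by design and classifier
  agreement must be 100%, not merely high.
* **Annotations** — iHS ~ Normal(0, s) per population with s set so the
  null tail beyond |2.5| equals `ihs_tail_frac` (default 0.0124, the
  standard-normal mass); changing SNPs get `planted_ihs_shift` (default
  0.1) added to |iHS|; 30% of SNPs lack a score, mimicking partial
  coverage. Disease flags are Bernoulli with a log-odds offset
  log(`planted_or_disease`) for changing SNPs, at a 0.2% baseline
  (GWAS-catalog-like) and a 7% baseline (ClinVar-like). SIFT-style
  deleterious flags are independent of change status at rate 0.18.
* **Expression** — genotypes Binomial(2, maf) with maf ~ U(0.05, 0.5)
  (Hardy–Weinberg, no linkage disequilibrium); genes group 1–3 consecutive
  SNPs; an `eqtl_frac` (default 0.1) of changing-SNP genes receives
  β ~ Normal(0, 1) on the dosage of its first changing SNP, everything
  else is unit-variance noise.

What the generator does **not** emulate: codon structure, linkage
disequilibrium, population stratification, allele-frequency spectra,
expression covariates. Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated — that planted effects of
realistic magnitude are recovered and null plants are not rejected above
the nominal rate — not that any particular biological conclusion holds on
real data.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based only at the VCF
  boundary. Scanner output is ordered by (start, miRNA, type) and all
  stages are deterministic given (inputs, seed).
* Multi-allelic VCF records are split into per-alternate biallelic
  records; a SNP changes regulation if any ref/alt pair does. Minus-strand
  CDS records are reverse-complemented at the I/O boundary so every
  downstream module sees mRNA sense.
* The minimal VCF columns cannot carry the synonymous/nonsynonymous class;
  the reader accepts an optional INFO key `CLASS` and defaults to
  synonymous.
* Fisher's exact test, the Wilcoxon machinery and the large-n Spearman p
  are delegated to scipy; the exact small-n Spearman p is an in-package
  vectorised enumeration (the corresponding tests check both against
  independent enumeration oracles).
* Degenerate inputs: empty flank(s) are allowed down to an 8-nt window
  (the longest site class); below that is an error. Empty classification
  input yields an explicitly missing fraction, not 0/0.
* Desk-scale problem sizes used by the tests and the acceptance script
  (5,000 constructed SNPs; 47,039-SNP annotation-only simulations; 50
  replicates for coverage checks; 2,000–10,000 permutations) were chosen
  so every distributional check has comfortable statistical resolution at
  interactive runtimes.

## Known limitations

* Seed-level binding is a coarse model of miRNA targeting: no non-canonical
  sites, no accessibility, no expression context. Site *presence* is also
  a weaker claim than site *function*, especially in coding regions where
  ribosome transit competes with RISC binding.
* A changed verdict depends on the supplied catalog and the counted site
  classes; enlarging either can only grow the bound sets, so changed
  fractions are not comparable across configurations.
* The gene-level expression screen inherits the any-SNP aggregation's
  anti-conservatism; its ORs are comparative, not effect estimates.
* Tail-count selection screens (|iHS| ≥ 2.5) need thousands of scored SNPs
  before the 2×2 cells are informative; at small n the permutation and
  Wilcoxon analyses are the useful ones.
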