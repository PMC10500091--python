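# Methods

## Problem and model

The package ranks candidate genetic disorders for a single patient by
fusing two independently computed signals:

1. a **gene score** in [0, 1] — the posterior probability that the gene
   harbours a pathogenic variant, obtained by ACMG-AMP evidence assignment
   and Bayesian combination;
2. a **phenotype score** in [0, 1] — the normalized similarity between the
   patient's HPO term set and each disease's annotated term set.

The fused score is the convex combination `γ·gene + (1−γ)·phenotype`. Both
inputs are optional: a phenotype-only query ranks purely on similarity, a
VCF-only query purely on gene evidence; the candidate universe is always
the full annotation corpus, so diseases without variant support still
compete (gene score 0) and vice versa.

## Ontology and information content

HPO is treated as a DAG over `is_a` edges only (the phenotypic-abnormality
subontology is is-a structured; terms can and do have multiple parents, so
a tree assumption would silently drop edges). Depth is the shortest is-a
path to the root; obsolete terms resolve through `replaced_by` and
`alt_id` maps at input time.

Information content is disease-frequency based on whatever annotation
corpus is supplied at run time:
`IC(t) = −ln(n_diseases annotated at-or-below t / n_diseases)`, natural
log (similarity ratios are base-invariant). Terms with no annotated
descendants get an `inf` sentinel: they are excluded as MICA candidates,
and term pairs touching such a term fall back to the topological
similarity alone, avoiding 0/0 in the IC-normalized ratio.

## Similarities, blending, normalization

* Topological: `2·depth(LCA)/(depth(t1)+depth(t2))`, LCA = deepest common
  ancestor (ties: lexicographically smallest ID). Equals 1 iff the terms
  coincide.
* Semantic (Lin over the MICA): `2·IC(MICA)/(IC(t1)+IC(t2))`; 1 for
  identical terms, 0 when the only common ancestor is the root.
* Set aggregation: symmetric best-match average — each patient term's best
  counterpart in the disease set and conversely, the two directional means
  averaged. Patient terms that are ancestors of other patient terms are
  kept; best-match aggregation is robust to that redundancy.
* Blend `β·top + (1−β)·semantic`, β default 0.9 (the topological component
  carries most weight; the semantic term refines among near-ties).
* Normalization: min–max across the candidate list per case, making the
  phenotype score commensurate with the gene posterior before fusion. When
  every blend is equal (e.g. a single candidate) all diseases score 1.0 —
  no information, no penalty.

Each of these four choices is isolated behind one function
(`top_similarity`, `meic_similarity`, `set_similarity`, the normalization
block in `PhenotypeScorer.score`) so an alternative formula is a local
swap.

## Variant screening

* α screen: keep AF missing or AF ≤ α (α default 0.1). The boundary is
  inclusive — borderline variants are left for the evidence engine to
  adjudicate. Missing AF is deliberately distinct from 0 and is treated as
  rarity (kept, PM2-eligible), matching standard interpretation practice.
* Inheritance screen, from single-sample genotypes and disease-linked
  modes only (no pedigrees): AD/XLD pass any genotype; AR requires ≥1
  homozygote or ≥2 distinct heterozygotes in the gene (an unphased
  compound-het heuristic with a documented over-call risk); XLR requires a
  hemizygote or homozygote, with heterozygotes accepted when sex is
  unknown. Genes without mode data pass through; unknown mode strings warn
  and count as no data. A qualifying gene keeps all its variants.

## Evidence rules and Bayesian combination

The rule table reads only fields present on the annotated input (gene-level
flags come from a small config: loss-of-function mechanism, missense
constraint, truncating mechanism, known pathogenic changes/residues,
hotspots). Rules lacking their inputs stay silent; every rule can be
disabled; precomputed evidence codes bypass the table. Thresholds: PM2
AF < 1e-4, BA1 AF > 0.05, PP3 in-silico ≥ 0.8, BP4 ≤ 0.2 (all
configurable). PM4 excludes repeat-region in-frame indels, which instead
feed BP3.

Combination uses exponentially tiered odds with a very-strong odds of 350
and prior 0.1; benign evidence enters as negative exponent terms
(supporting −1/8, strong −1/2) except BA1, which is stand-alone by
definition and overrides to benign/posterior 0 — exponent treatment would
let strong pathogenic evidence outvote it. Classification bands:
pathogenic ≥ 0.99, likely pathogenic ≥ 0.90, likely benign ≤ 0.10, benign
< 0.001. The gene score is the maximum posterior over the gene's variants
— the conservative choice consistent with monogenic diagnosis — again
isolated behind one function (`gene_scores`).

## Ranking and evaluation

Fusion is `γ·gene + (1−γ)·phenotype`, γ default 0.5 (equal weight on
commensurate [0, 1] scores). Ordering is total and deterministic: combined
score descending, then phenotype score descending (the patient-specific
signal), then disease ID. Gene rankings take each disease's best
supporting gene at its first appearance. Cohorts are summarized as
cumulative TOP-1/5/10/20/50 proportions plus a >50 band (absent causal
genes count as >50). Rank-vector comparison uses the one-sided Wilcoxon
signed-rank test (alternative: first vector smaller) with the zero-split
policy for ties and the normal approximation, so identical vectors yield
p = 0.5 rather than an error; n < 5 warns as underpowered.

## Synthetic data

The generator emulates a phenotype-plus-exome rare-disease cohort without
any restricted data:

* ontology: a `branching`-ary tree backbone (predictable depth ≈ log_b n)
  plus a random extra parent on ~25% of terms to exercise DAG paths;
  defaults n_terms = 150.
* corpus: 60 diseases × 6 distinct non-root terms, one causal gene and one
  inheritance mode each (AD/AR on autosomes, XLD/XLR on X; ~10% of genes
  X-linked).
* cases: the causal disease's terms perturbed by independent per-term
  probabilities p_drop / p_generalize (replace by a parent) / p_add;
  a case whose term set empties is skipped with a warning.
* variants: one spiked causal variant (stop-gain, AF missing, genotype
  consistent with the mode, in a loss-of-function-mechanism gene → PVS1 +
  PM2) plus 30 background variants that are benign-profile by
  construction — half common polymorphisms (AF 0.11–0.5, removed by the α
  screen) and half rare synonymous variants (AF 1e-3–1e-2, BP7 and
  sometimes BP6), mirroring a healthy-exome background.

All randomness flows from one seed through named substreams
(ontology / corpus / per-case), so identical configs give byte-identical
fixtures across runs and platforms.

What the generator does **not** emulate: realistic genome coordinates or
sequences, linkage between background variants and phenotypes, HPOA
frequency/onset modifiers, negated phenotypes, multi-gene diseases,
phasing, pedigrees. Passing tests therefore demonstrate the correctness
and determinism of the scoring machinery and its graceful degradation
under phenotype noise — not clinical performance on real cohorts, where
annotation quality and phenotype ascertainment dominate.

## Problem sizes and numerical choices

The test suite and the acceptance script use 500-case cohorts over 60
diseases and 150 terms — large enough that recovery statistics are stable
(chance TOP-5 ≈ 8%), small enough to run in seconds. Evidence-combiner
equivalence is checked exhaustively over the full 2160-point evidence
lattice at 1e-12. Min–max normalization treats spans ≤ 1e-12 as
degenerate. Floating-point AFs read from VCF are float32; comparisons in
tests use approximate equality accordingly.

## Known limitations

* The compound-het rule over-calls when two heterozygous variants are in
  cis; resolving this needs phase or parental data, which is out of scope.
* PS2/PS3/PM3/PM6/PP1/PP4/BS3/BS4/BP2/BP5 are not scored — they require
  segregation or functional data absent from the supported inputs.
* The gene score ignores zygosity beyond the inheritance screen; a
  compound-het pair contributes only its best variant.
* Phenotype normalization is per-case min–max, so a phenotype score is
  comparable across diseases within one case, not across cases.
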