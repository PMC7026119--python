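# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `famvarseg`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The study design being modelled

The package targets the multiplex-family exome design: 27
multigenerational families densely affected with bipolar disorder (BD),
three affected members per family selected for sequencing so as to be as
distantly related as possible, followed by Sanger-style genotyping of all
DNA-available relatives for the prioritized variants. Because only allele
sharing is observed, the analysis rests on the rarity argument that for
alleles below 0.1% population frequency, identity by state among relatives
is effectively identity by descent.

## Prioritization cascade

All filters are conjunctive, so the candidate set is independent of
application order, and relaxing any single threshold can only grow it
(both properties are under test).

* **Genotype quality.** A heterozygous call requires site depth ≥ 10 and
  alternate-read fraction within [0.25, 0.75]. Both allele-balance bounds
  are *inclusive* — the natural reading of "between 25% and 75%" — and are
  config fields (`FilterConfig.ab_min/ab_max`). Zero-depth calls fail
  rather than raising. The depth requirement applies to every sequenced
  member; since the sharing step already demands a passing het call in all
  of them, a carrier-only depth rule would collapse into the same
  behaviour (`depth_in_all_members` exposes the looser variant anyway).
* **Sharing.** A variant must be het-called in *all* sequenced affected
  members of the family. This deliberately targets high-penetrance alleles
  and knowingly discards lower-penetrance ones.
* **Consequence.** Missense, stop-gain, frameshift, in-frame indel, or
  splice. Synonymous and non-coding classes fail.
* **Reference MAF.** Strictly below 0.1% against the reference exome
  panel; a variant absent from the panel passes (it is rarer than
  anything the panel can certify).
* **Deleteriousness consensus.** Substitutions: ≥ 3 damaging or
  possibly-damaging calls (D/P) over the fixed 5-tool panel {SIFT,
  PolyPhen-2 HumDiv, PolyPhen-2 HumVar, LRT, MutationTaster}. `NA` and
  `U` count as non-damaging votes with the denominator fixed at the panel
  size — the conservative convention, and the one consistent with
  fixture rows that pass on exactly 3 votes with an `NA` in the grid.
  InDels: ≥ 1 of {MutationTaster, PROVEAN, SIFT}; frameshifts are routed
  through this rule, not the stop-gain rule. Stop-gain substitutions:
  MutationTaster must call D, irrespective of the other tools (which
  typically return `NA` for nonsense changes). Exhaustive enumeration of
  all 5-tool grids (5⁵ = 3125; 992 pass) is an acceptance check.

## Cosegregation classification

The published analysis describes "full or nearly full cosegregation"
qualitatively; the package formalizes it as: a gene is **HIGH** iff in
every family `bd_carriers ≥ bd_total − 1` *and* `unaff_carriers ≤ 1`;
otherwise **LOW** ("several unaffected carriers" = ≥ 2 in any single
family). Other-psychiatric relatives are neutral — they count as
unaffected only in the association test's coding, where all non-BD
diagnoses are unaffected. This is the minimal rule reproducing the
published 5 HIGH / 3 LOW split, and both tolerances are parameters
(`max_affected_noncarriers`, `max_unaffected_carriers`). No numeric
penetrance is estimated: the carrier counts are far too small.

Brain expression: a gene is brain-expressed iff its mean over exactly 12
brain regions (spinal cord excluded) strictly exceeds 0.5 RPKM; missing or
unexpected regions are errors naming the region. Expression values are a
plain input table; the packaged 12-region table is synthetic, constructed
only to reproduce the published per-gene flags.

## Gene-dropping association test

The published study ran an external founder-score pedigree association
tool; only two nominal p-values and the Bonferroni step are printed. The
package therefore implements a *documented stand-in* sharing the same
inputs and correction rather than re-deriving that tool's statistic:

* statistic: `#affected carriers − #unaffected carriers` among genotyped
  members, affected = BD-I/II/NOS, everything else unaffected;
* null: a single heterozygous allele introduced at a founder chosen
  uniformly, transmitted with probability 1/2 per meiosis (vectorized over
  simulations), conditioned on ≥ 1 genotyped carrier — the variant was,
  after all, observed. An alternative conditioning ("all sequenced members
  carry") is a config switch;
* p-value: add-one empirical, `(1 + #{null ≥ observed}) / (n_sims + 1)`,
  hence never exactly 0 and never below `1/(n_sims+1)`;
* correction: `min(1, n_tests × p)` with `n_tests` = number of variants
  tested (16 for the fixture tables).

Every output row carries a `method` tag identifying the stand-in. Tests
check the Monte Carlo p against exhaustive enumeration (founder choice ×
2^transmissions) on a nuclear family within 3 Monte Carlo standard errors
at 10⁶ simulations, and that null-generated phenotypes give a
conservative (stochastically ≥ uniform) p distribution over 500
replicates.

## Kinship screening

Eligible sites are rare (the same MAF rule as the cascade), within 100 bp
of a capture-target interval (interpreted as interval padding in 0-based
half-open arithmetic; the upstream tool's exact semantics are
undocumented), and — when a FILTER column is present — recalibration
passes. Sharing for a pair is `|A ∩ B| / |A ∪ B|` over the pair's eligible
sites; the union denominator is recorded in the output because the
upstream tool's denominator is likewise undocumented. Allele matching is
exact (chrom, pos, ref, alt) identity by state. Pairs with an empty union
report fraction 0 with a warning flag. Cross-family pairs above a 3%
alert threshold are flagged; relationship-degree classification is out of
scope.

## Matched permutation enrichment

Null lists are drawn 1:1 per candidate ("matched with our candidate
genes" read literally; a set-level mode exists as config): the i-th null
gene is uniform over non-candidate genes within ± 20% relative exon
length, ± 20% relative coverage and ± 0.5 absolute constraint *z* of
candidate i. The *z* tolerance is absolute with staged ×2 relaxation (up
to 3 times) because *z* is unbounded and a relative window is ill-defined
near 0; the paper states no z tolerance at all. If the window is still
empty — which happens for covariate-extreme candidates in scaled-down
universes of a few thousand genes, though essentially never in a full
exome — the proportional windows widen ×1.5 per additional stage (up to 3
more) before erroring, and the sampler records the per-candidate
relaxation stage so post-hoc matching validity is assertable.

Within one permutation the null genes are distinct; candidates are visited
scarcest-pool-first so a candidate with few matches is not starved by
earlier draws, with the fully relaxed window as a last-resort pool.
Across permutations draws are independent. One null list per permutation
is scored against *all* gene sets, and Benjamini–Hochberg is applied
jointly across the resulting p-values (mirroring a single correction over
all tested sets). Empirical p-values are add-one, consistent with a
`< 1/(N+1)` floor at N = 10,000. The BH step itself is delegated to
`scipy.stats.false_discovery_control`; the test suite checks it against an
independently coded step-up formula. Genes without covariates raise a
`MatchingError` naming the gene.

## Synthetic cohort generator

The generator's defaults *are* the study conditions; they are not tuned
per experiment.

| parameter | default | rationale |
|---|---|---|
| `n_families` | 27 | cohort size of the modelled study |
| `n_sequenced_per_family` | 3 | affected members sequenced per family |
| `pedigree_depth` | 3 generations | "multigenerational" |
| `mean_children` | 2.6 | sibship 1 + Poisson(1.6); multiplex-scale families (typically 6–18 members) |
| `causal_gene_count` | 8 | recurrent candidate genes; assigned round-robin so every causal gene is injected into ≥ 2 families |
| `causal_penetrance` | 0.9 | high but incomplete penetrance; carriers affected with this probability |
| `phenocopy_rate` | 0.01 | BD lifetime prevalence ~1%; non-carriers affected at this rate |
| BD-I : BD-II : NOS | 69 : 9 : 3 | diagnosis split of the 81 sequenced cases |
| `background_variant_rate` | 0.37 per gene per founder | calibrated (pilot runs over four seeds, then frozen) so the full cascade yields ~14 candidate variants per family, the study's 378/27 yield |
| `maf_spectrum` | 30% absent-from-panel, log-uniform 10⁻⁶–10⁻² tail | matches the fixture tables' mix of `NA` and printed MAFs |
| `prediction_error_rate` | 0.05 | per-tool probability that a causal variant's damaging call is flipped |
| background damaging rate | 0.2 per tool | chosen so the 3-of-5 consensus is discriminative (~6% SNV pass rate) |
| `depth_mean` | 60 | mean exome coverage ~68×; Poisson depth, Binomial(depth, ½) alt reads |
| `n_genes` | 4000 | compressed exome; large enough that ~370 candidate genes leave a matchable null universe |
| `n_shared_pool` | 500 | cohort-wide low-frequency alleles (founders carry at Hardy–Weinberg rates) giving unrelated families a non-zero sharing signal |
| `other_psy_rate` | 0.08 | fraction of non-BD members with another psychiatric diagnosis |
| `dna_available_rate` | 0.85 | relatives genotypable in the extended segregation step |

Sequenced trios are the three DNA-available affected members minimizing
summed pairwise kinship (computed by the standard recursive kinship
algorithm), ties broken lexicographically. Each causal variant enters a
family through exactly one founder; Mendelian consistency (no carrier
without a carrier parent, bar the introduction) is a tested invariant.
Per-family random substreams derive from
`SeedSequence([seed, family_index])`, so adding families never perturbs
earlier ones, and a fixed seed reproduces byte-identical files.

Because the pedigrees are small (and the gene universe compressed), the
per-founder background rate is far higher than a real per-gene mutation
load; it is a calibration device for the *downstream* yield, not a
population-genetic quantity. The generator also omits linkage
disequilibrium, X-chromosome inheritance, read-level artifacts and
population structure — so passing tests demonstrate the pipeline's
correctness and calibration under the stated generative model, not
robustness to those real-data complications. The real families' structures
are not public; the synthetic pedigrees are stand-ins and no claim of
matching them is made.

For the recovery and spiked-enrichment experiments the cohort is run at
`causal_penetrance = 1.0` with `phenocopy_rate = 0`: these experiments
isolate the cascade's sensitivity, and a phenocopy selected into a trio
would by design break the all-members sharing requirement — a property of
the selection step, not of the filters under test.

## Problem sizes and numerics

* Gene-drop acceptance comparison: 10⁶ simulations against a 32-outcome
  exhaustive enumeration, 3-standard-error tolerance.
* Enrichment calibration: 200 null replicates at N = 1,000 permutations
  (scaled down from the 10,000 used for reported runs); rejection at
  α = 0.05 bounded by 0.05 + 3 s.e. The add-one estimator plus matched
  sampling makes the test conservative in practice.
* Spiked-set detection: 10 replicate analyses of the full 27-family
  cohort; rejection required in ≥ 90%.
* Monte Carlo comparisons elsewhere use 3-standard-error bands from
  binomial oracles.
* All p-values are add-one; none can be 0. Fractions with empty
  denominators (kinship pairs with no eligible sites) report 0 with a
  warning flag rather than NaN.
* Coordinates: VCF and all in-memory positions 1-based; BED intervals
  0-based half-open; the only conversions live in the BED reader and the
  kinship padding check.

## Known limitations

* The association stand-in is not the published founder-score statistic;
  corrected values match the printed ones exactly only because they are
  arithmetic on the printed nominal p-values.
* HIGH/LOW classification is a formalized reading of qualitative
  language; families with very few genotyped relatives are classified on
  thin counts, and the package deliberately reports counts alongside the
  class.
* The kinship screen is identity-by-state sharing only — adequate for
  "are these families cryptically related?", not for degree estimation.
* Whether individuals with other psychiatric disorders should penalize
  cosegregation is interpretive; here they are neutral for classification
  and unaffected for association, and both choices are config-visible.
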