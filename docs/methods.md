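# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Cohort model

The package targets a case-only gene-panel design: *n* unrelated affected
individuals plus a small number of affected sib-pairs (defaults 164 + 5 pairs
= 174 cases), sequenced over a fixed panel (default 101 genes). There are no
controls; inference about per-gene excess leans entirely on external
background carrier probabilities, and phenotype analyses are within-cohort.

## Filter cascade

A variant site qualifies when it passes, in order:

1. **Quality** — read depth > 10, RMS mapping quality > 40, quality-by-depth
   > 2, all strict. A missing quality field rejects the variant with a logged
   warning rather than guessing.
2. **Cohort rarity** — at most one homozygous-or-hemizygous carrier AND at
   most two heterozygous carriers in the cohort. The conjunction (rather than
   "one hom OR two het") is the reading consistent with an allele-count cap of
   two (~0.5% cohort MAF); the disjunctive reading would admit unlimited
   heterozygotes. Hemizygous male calls on X-linked genes count in the
   homozygous cap (one allele present ≈ functionally homozygous).
3. **Reference rarity** — every MAF that is present (1000G-EUR, ExAC,
   in-house) must be < 0.05, strict. A missing MAF passes: absence from the
   databases is itself rarity evidence. This knowingly admits
   population-specific founder variants; that is a property of the design,
   not a bug of the implementation.
4. **Effect** — `rare_all` keeps all non-synonymous coding classes (missense,
   stop-gained, frameshift, canonical splice, in-frame indel);
   `rare_predicted_damaging` further requires LoF or damaging missense
   (CADD phred ≥ 20 OR meta-SVM "damaging" — an OR, so a single tool
   suffices); `known_pathogenic` keeps ClinVar/HGMD-flagged variants that
   pass quality, regardless of rarity or prediction.

Whether burden-type analyses should use `rare_all` or
`rare_predicted_damaging` is genuinely ambiguous in this study design; both
are exposed as modes and nothing downstream assumes one of them.

Canonical-transcript handling: the annotation schema carries one row per
variant-transcript. An optional `canonical` column selects the row; otherwise
the lexicographically first transcript is taken deterministically (the schema
carries no transcript length, so a longest-transcript fallback is not
implementable from the inputs). Multi-allelic VCF records are decomposed into
bi-allelic entries before filtering, since every rule is per-allele.

The carrier matrix counts *variants* per individual and gene (a homozygous
call is one variant carried, not two alleles); carrier *flags* (≥ 1 variant)
derive from it where a test needs them.

## Carrier-excess (SORVA-style) test

For gene *g*, let `p_g` be the background probability that a reference
individual carries ≥ 1 qualifying rare variant (user-supplied panel column;
the original background database is an external download). With *k* carriers
among *n* unrelated cases the p-value is the exact binomial upper tail
`P(X ≥ k | n, p_g)` via the survival function. Sib-pairs are excluded from
*k*/*n* and reported as shared events *s*/*n_sib* (both sibs carrying ≥ 1
qualifying variant in the gene): siblings are not independent draws, and no
sib likelihood is specified for this design, so folding them in would be
pseudo-replication. `p_g = 0` with `k > 0` is reported as p = 0 with a
warning (model violation). Raw p-values are reported by default, matching how
such scans are usually published; a Bonferroni flag corrects over the panel.

Monotonicity (strictly decreasing in *k* and in `p_g`) and equality with
brute-force pmf summation to 1e−12 are enforced by tests.

## RVIS-weighted burden and phenotype association

`w_g = 1 − RVIS percentile/100` maps genic intolerance to [0, 1); burden is
the weighted count `B_i = Σ_g v_ig w_g`. Siblings are scored separately —
different rare variants may underlie each sib's phenotype. Association uses
OLS (`scipy.stats.linregress`; slope p from t with n−2 df) and two-sample
t-tests, Welch by default because equal variances are never guaranteed across
sex or syndromic strata (a pooled-variance flag exists). The
calibrated-severity transform (ADOS raw total → 1..10 by age band and module)
is a deterministic lookup in a user-supplied table; out-of-range raw totals
clamp to the nearest band with a warning rather than failing a whole cohort
for one extreme score.

## Mutual-information kernel and clustering

Similarity between two individuals is the plug-in MI of their binary
questionnaire vectors over the empirical 2×2 joint, in bits (base
configurable to nats; bits are conventional for binary variables). The
convention 0·log 0 = 0 applies, and the estimate is clipped at 0 against
round-off. Missing responses are dropped pairwise; individuals with > 50%
missing items (configurable) are excluded with logged ids. The kernel
diagonal is each individual's response entropy. For complete matrices the
whole kernel is computed by four matrix products over the item axis; the
scalar per-pair path is retained for missing data and serves as the oracle in
tests.

Clustering is Ng–Jordan–Weiss: eigenvectors of `D^(−1/2) S D^(−1/2)` for the
top k eigenvalues, rows unit-normalized, then k-means (k-means++ with 50
restarts and a fixed seed, so the pipeline is deterministic end to end). The
raw MI matrix is used as the affinity with no bandwidth or rescaling — the MI
kernel *is* the similarity, and adding a scale would introduce an
unmotivated tuning knob. k defaults to 4, the small cluster count appropriate
for cohorts of this size. A similarity graph with more connected components
than clusters raises an error rather than returning an arbitrary split.
Zero-degree individuals (constant response vectors have zero MI with
everyone) receive zero embedding rows.

Kernel PCA double-centres the kernel, eigendecomposes, and scales
eigenvectors by √λ. The MI matrix need not be positive semi-definite;
negative-eigenvalue components are discarded with a logged count, the
standard treatment of indefinite similarities. Signs are fixed by forcing
each component's largest-magnitude entry positive, making embeddings
reproducible. Three dimensions are the default (visualization). The
implementation is cross-checked in tests against scikit-learn's
`KernelPCA(kernel="precomputed")` up to sign, and the spectral pipeline
against `SpectralClustering(affinity="precomputed")` on planted data; both
remain independent checks, not the implementation.

Binarization of raw questionnaires is rule-driven per item (already-binary,
threshold on counts, category membership) and deliberately config-exposed:
no canonical rule set exists for arbitrary clinic questionnaires, so the
package refuses to guess, and errors list every item lacking a rule.

## Cluster–gene enrichment

Per gene, one-way ANOVA of per-individual variant counts across clusters
(counts, not flags, by default — aggregation on genes is count-like — with a
carrier-flag option), plus pairwise Welch t-tests. Bonferroni families are
explicit and conservative: ANOVA over the testable genes; pairwise over
genes × cluster-pairs, reported separately. Genes with zero variance
everywhere are untestable and reported as such. With two clusters the ANOVA F
equals the squared pooled t statistic, which the tests enforce to 1e−10.

The syndromic-by-cluster table is tested against expected counts proportional
to cluster sizes: chi-square when all expected counts are ≥ 5, otherwise an
exact multinomial goodness-of-fit (enumeration of all compositions, summing
the probability of every table no more probable than the observed one). With
two cells this reduces to the two-sided exact binomial test, which is the
cross-check used in the tests.

## Synthetic-data generator

The generator emulates exactly the statistical structure the analyses
assume:

* **Genotypes** — individual × gene carrier events are independent
  Bernoulli(`p_g` × multiplier); each event is one heterozygous SNV at its
  own site with placeholder A→G alleles (downstream statistics depend only
  on carrier/variant counts, so haplotypes, allele identity, zygosity
  diversity, LD and recurrent mutation are deliberately not modelled). Each
  sib-pair carrier event posits one heterozygous carrier parent; each sib
  inherits independently with probability 1/2, the simplest Mendelian
  sharing model consistent with separate `s/n_sib` accounting. All
  individuals are cases (case-only design).
* **Qualities and annotations** — drawn to pass the filter (RD 60–200,
  MQ 50–60, QD 5–30; missense, CADD 21–40, SVM damaging, MAFs 0), so the
  generator's carrier matrix round-trips through the filter cascade
  identically under both rare modes. Records that must *fail* (low RD/MQ/QD,
  synonymous, common) are injected on request and never enter the truth
  matrix.
* **Questionnaires** — a Bernoulli mixture: 4 clusters over 149 items, the
  first 30 items discriminative with per-cluster probabilities of 0.9 or 0.1
  (an independent fair-coin pattern per cluster, fixed by a pattern seed),
  remaining items background at 0.3. This is the strong-separation regime:
  two clusters disagree on about half the discriminative items.
* **Phenotypes** — ADOS raw total = intercept + slope · burden + Gaussian
  noise (defaults 20 + 0·B + N(0, 5): severity unlinked to burden unless a
  link is planted); malformation counts Poisson(5); sex Bernoulli at the
  129:45 male fraction; ages 2 + Poisson(4) years (child cohort, median ≈ 6);
  syndromic flags at rate 13/174 with 4/13 of those screen-detected.

Fixed seeds make every output byte-identical. What passing tests on these
cohorts show is that the *pipeline* is correct and well-calibrated under its
own model; they cannot show that real questionnaires are Bernoulli mixtures,
that real carrier events are independent across genes, or that real quality
annotations are clean — on real data the filter cascade and missing-data
handling carry correspondingly more weight.

## Problem sizes in the test suite

Sampling-based tests use sizes chosen to make the assertions sharp while the
whole suite stays interactive (~10 s): binomial recovery at n = 2000,
200-replicate calibration checks for the carrier-excess scan and the
enrichment FWER/power at 101 genes × 160 individuals (vectorized ANOVA/t
across genes), 20-seed planted-cluster recovery at 160 individuals × 149
items, and a 200-individual, 101-gene simulator/filter round trip.

## Known limitations

* The carrier-excess test conditions on user-supplied background
  probabilities; mis-specified `p_g` propagates directly into the p-values.
* Sib-pair shared events are described, not tested; a likelihood for sibling
  sharing is out of scope.
* Plug-in MI is positively biased at few items (~1/(2·m·ln 2) bits); with
  149 items this floor is ≈ 0.005 bits, which compresses contrast between
  weakly associated individuals. No bias correction is applied, keeping the
  kernel exactly the plug-in estimate.
* The exact multinomial test enumerates compositions and is only intended
  for small tables (N ≲ 30, k ≲ 6).
* Kinship is taken from declared family ids, never inferred from genotypes.
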