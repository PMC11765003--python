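# Methods

## Problem setting

Cell-free DNA (cfDNA) in maternal plasma is a mixture: a fraction *f*
(typically 3–20%) derives from the placenta and carries the fetal genotype,
the rest from the mother. For an autosomal recessive disorder such as
β-thalassaemia, the clinically decisive question reachable without dosage
analysis is which **paternal** haplotype the fetus inherited: at sites
where the mother is homozygous and the father heterozygous, one paternal
allele is absent from the maternal background, and its reads in plasma are
attributable to the fetus. `niph` turns per-site allele read counts into
that inheritance call and a diagnostic interpretation.

## Site classification

Each biallelic panel site falls into one of four parental-genotype groups
per family:

| group | mother | father | use |
|---|---|---|---|
| i (informative) | hom | het | fetal-specific allele detection |
| ii (cut-off) | hom | hom, same allele | error-rate calibration |
| iii (fetal presence) | hom | hom, different allele | fetal-DNA presence check (reported, not called by default) |
| iv (maternal het) | het | any | excluded (no fetal-specific allele; dosage methods out of scope) |

Sites with any missing parental genotype are unusable. Pathogenic HBB
variants are carried through the same machinery as pseudo-sites keyed by
their HGVS name: when the parents carry *different* variants, the father's
variant site is itself group i and the pathogenic allele is detected
directly.

## Fetal fraction, error rate, and the cut-off

The central statistic is ff(%) = 2p/(p+q)·100 with *p* the fetal-specific
(or unexpected, or minor) allele count and *q* the shared-allele count.
At group-i sites its expectation is ~100·f when the fetus carries the
fetal-specific allele; at group-ii sites, where any non-parental read is an
artefact, it measures the error rate (expectation ~200·ε for a symmetric
per-read flip probability ε).

Each cfDNA replicate is calibrated independently — replicates are never
pooled — as cut-off = max(group-ii error rates) + *m*·SD, with the sample
SD (n−1 denominator; the table structure of the validation data implies
per-replicate calibration, and the SD convention is our choice as the
source is silent) and multiplier *m* = 1 by default (configurable;
the +1 SD rule was the empirically better of the variants compared during
validation). Calibration requires ≥ 2 group-ii error rates and fails
loudly otherwise. A site is called **positive** iff ff strictly exceeds
the cut-off; ff equal to the cut-off is negative ("exceeding" is read
literally).

## Truth labelling and accuracy

Where a chorionic-villus (CVS) genotype exists, truth at an informative
site is *present* iff the CVS carries the fetal-specific allele; calls are
labelled TP/FN/TN/FP and pooled **per SNV across families** (not averaged
per family). Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP);
95% CIs are exact Clopper–Pearson intervals from beta quantiles, with the
FNR/FPR intervals as complements. Note the validation cohort's
false-positive rate is 3/258 = 1.16%, which rounds to 1.2% although the
source text prints 1.1%; the package reports the recomputed value.
Display rounding is half-up at the precision of the corresponding report
table; underlying values keep full precision.

## Paternal phasing and inheritance

Three phase sources, tried in the order explicit file > CVS >
grandparents:

* **CVS**: at each informative site the transmitted paternal allele is the
  fetal allele not attributable to the (homozygous) mother; transmitted
  alleles form one haplotype, untransmitted the other. Anchoring to
  wild-type/pathogenic uses the paternal pathogenic variant: resolvable
  when the mother is homozygous there or the CVS is homozygous; a shared
  parental variant with a heterozygous CVS cannot be anchored and the
  caller is directed to an external phase.
* **Grandparents** (the prospective clinical route): at each paternal het
  site the allele origin is assigned when Mendelian transmission is
  unambiguous (at least one grandparent informative); ambiguous sites stay
  unphased and are excluded from voting; a parental allele absent from
  both grandparents raises a Mendelian-inconsistency error naming the
  site. The haplotype from the grandparent who contributed the pathogenic
  variant is the pathogenic one.
* **External phase table** from a previous family study (TSV of site,
  wild-type allele, pathogenic allele), checked against the father's
  genotypes. Recombination between panel sites is neglected — the panel
  spans one gene cluster.

Each informative call votes: positive for the haplotype carrying the
fetal-specific allele, negative for the other haplotype (negative votes
are load-bearing: families whose fetus inherited the allele-free haplotype
are resolved purely by true negatives). The inherited haplotype needs a
strict majority (> 50%); an exact tie is inconclusive; zero informative
sites is not-applicable. One informative SNV suffices by default
(`min_informative` is configurable; a concordance floor is likewise
exposed but defaults to the >50% rule, as the validation work did not fix
a higher threshold). Replicates that disagree on the winner yield a
family-level inconclusive. Diagnosis: wild-type inherited → invasive
sampling avoided (the fetus is at most a carrier); pathogenic inherited →
invasive confirmation recommended; the maternal haplotype is never
inferred.

## Panel selection

From a cohort genotype matrix, per site (missing genotypes excluded from
every denominator): near-monomorphic sites (> 95% homozygous reference,
strict) are *common*; observed heterozygote frequency strictly above 90%
flags a non-Mendelian genotyping artefact; within the inclusive 10–90%
window, sites must pass a Hardy–Weinberg goodness-of-fit test (χ² with
1 df against expectations from the sample allele frequency, no continuity
correction; p strictly above 0.05). The 10–90% "degree of heterozygosity"
is the observed per-individual heterozygote frequency, not expected
heterozygosity — only the observed frequency can exceed 90% as an
artefact signature. A conditional exact HWE test is available via
`method="exact"`; χ² is the default as the minimal defensible reading of
the validated procedure. Monomorphic sites get p = 1 by convention. Sites
below the window that are not hom-ref-common (e.g. mostly hom-alt) get a
dedicated `excluded_low_het` status so the statuses partition every input
site. A separate MAF filter (minor allele frequency strictly above 1%)
applies when candidates come from population databases.

## Synthetic data

No raw sequencing data accompanies the validation study, so generators
produce statistically matched stand-ins; all are bit-reproducible under a
fixed seed (`numpy.random.default_rng`).

* **Cohort**: genotypes drawn from HWE proportions per site.
  `simulate_structured_cohort` builds a 660-site screen-shaped cohort with
  exact class counts (324 common / 65 heterozygote-excess artefacts / 52
  HWE-violating / 219 conforming), guaranteeing membership by
  construction: common sites get ≤ 4/96 off-reference genotypes,
  artefact sites ≥ 87/96 heterozygotes, HWE violators a heterozygote
  deficit verified against the test, conforming sites HWE draws verified
  to pass. Selection over this cohort therefore reports those counts
  deterministically.
* **Family**: parental haplotypes drawn per site at the configured allele
  frequency (default 0.5, so that informative and cut-off sites are
  plentiful); the fetus inherits a chosen paternal haplotype and a random
  maternal one; CVS equals the fetal genotype; grandparents are generated
  consistently with the parental haplotypes. cfDNA counts per site: total
  reads Poisson with mean `depth` (default 10,000, the assay's coverage
  target; negative-binomial overdispersion optional), allele identity
  binomial with success probability (1−f)·m/2 + f·c/2 (m, c = maternal and
  fetal alt-dose) flipped with probability ε (default 0.003, chosen so
  simulated per-replicate maximum error rates span the 0.2–1.7% range seen
  in the validation replicates). By default the father is a heterozygous
  carrier of a pathogenic variant the mother lacks, placed on his
  pathogenic haplotype.
* **Spike**: informative mixture sites (major DNA homozygous, minor
  heterozygous); the minor-specific allele has read probability s/2
  (ε-adjusted), so the ff statistic recovers the spike fraction s in
  expectation.

What the generator does **not** model: amplicon-to-amplicon efficiency
bias, GC effects and dropout, read-level artefacts, or maternal somatic
variation. Consequences worth knowing: simulated spike bands are much
narrower than the published ones (which show SDs of 0.96–2.87% and a
downward mean bias, e.g. 8.55% measured at a 10% spike), and with ε > 0
the simulated minor fraction is inflated by ~2ε. Passing simulation tests
therefore demonstrates the correctness of the statistics and decision
logic, not the noise characteristics of a real amplicon assay.

## Numerical and design choices

* Strict inequalities follow the validated wording everywhere: "more than
  95%" (common), "higher than 0.05" (HWE), "exceeding the cut-off"
  (positive call), "> 50%" (majority); the heterozygosity window is
  inclusive at both ends; spike bands are closed intervals.
* Published summary tables were rounded column-wise, so re-derived sums
  (max + SD, mean ± SD) can differ from printed values by one unit in the
  last printed decimal; comparisons are made at printed precision.
* Reported percentages round half-up (`round_half_up`), matching the
  report tables; Python's banker's rounding is never used for display.
* Clopper–Pearson bounds come from beta quantiles with the exact 0/100%
  boundary conventions; tests cross-check them against an independent
  bisection of the binomial CDF.
* Group-iii sites generate no calls by default, mirroring validated
  behaviour (none were observed there); group-iv sites are always
  excluded from calling.
* Coordinates are 1-based in VCF/TSV, half-open 0-based in BED, converted
  only at I/O boundaries; only biallelic SNVs are accepted, others are
  skipped with a logged count. Upstream variant-calling settings (e.g. a
  mapping-quality threshold) are recorded in configuration for provenance
  but not applied — the pipeline consumes allele-depth tables produced
  downstream of alignment and variant calling.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use 100–400-site panels, 10,000× depth, and 40–200
seeded replicates; these sizes make every Monte-Carlo check (3-SE
parameter recovery, ≥ 99% end-to-end haplotype recovery at f = 0.03,
< 5% zero-fetal-fraction positive rate) stable while keeping the whole
suite in seconds.

## Known limitations

Maternal inheritance (group-iv dosage analysis) is out of scope, so a
fetus inheriting the paternal pathogenic haplotype always requires
follow-up. The error model is symmetric and site-independent; real
assays show site-specific error. The exact set of HWE-failing sites in
the original 660-site screen cannot be reconstructed without the raw
data; only the procedure and its operating point are reproduced.
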