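# niph — non-invasive prenatal haplotyping of the paternal allele

`niph` implements a cfDNA analysis pipeline for non-invasive prenatal
testing (NIPT) of autosomal recessive single-gene disorders, built around
β-thalassaemia and the HBB / β-globin gene cluster. Cell-free fetal DNA
makes up roughly 3–20% of the DNA in maternal plasma; at SNVs where the
mother is homozygous and the father heterozygous, one paternal allele is
absent from the maternal genome, and reads of that *fetal-specific* allele
reveal which paternal haplotype the fetus inherited — without invasive
sampling. The package is for scientists developing or evaluating such
assays: it covers panel design from a population cohort, per-family
calling from allele-depth tables, haplotype-based diagnosis, accuracy
statistics, and a synthetic-data generator for the whole chain.

## The statistics at the core

For read counts *p* (fetal-specific allele) and *q* (the allele shared by
mother and fetus) at one site:

    ff(%) = 2p / (p + q) × 100

estimates the fetal fraction, since a heterozygous fetus carries the
fetal-specific allele on one of its two chromosomes. The same formula at
sites where **both parents are homozygous for the same allele** — where the
other allele is biologically impossible — measures the assay's error rate.
Each cfDNA replicate is calibrated on its own:

    cut-off = max(error rates) + 1 SD(error rates)

and the fetal-specific allele is called present wherever ff strictly
exceeds the cut-off. Calls are scored against chorionic-villus (CVS)
genotypes where available; pooled counts give sensitivity/specificity with
exact (Clopper–Pearson) 95% confidence intervals. Finally each informative
site votes for the paternal haplotype consistent with its call, and a
strict majority (> 50%) determines the inherited haplotype: wild-type →
invasive testing avoided; pathogenic → invasive confirmation recommended.

Panel selection from a cohort keeps sites with an observed heterozygote
frequency between 10% and 90% (higher values are non-Mendelian genotyping
artefacts) that do not deviate from Hardy–Weinberg proportions
(χ², 1 df, p > 0.05); near-monomorphic sites (> 95% homozygous reference)
are set aside as uninformative.

## Worked example

```bash
python examples/analyze_family.py
```

```
panel: 101 sites; i_informative=26, ii_cutoff=10, iii_fetal_presence=13, iv_maternal_het=52
replicate demo_r1: cut-off = 0.801 + 0.093 = 0.894% (max group-ii error rate + 1 SD)
  12/26 informative sites called positive; vote 26/26 (100%) for hap_path
simulated transmission: path; inferred: hap_path
verdict: invasive_recommended
```

A simulated trio (fetal fraction 5%, 10,000× coverage, per-read error
0.003) is analyzed end to end. Ten sites where both parents share the same
homozygous genotype calibrate the replicate's cut-off at 0.894%. Of the 26
informative sites, the 12 whose fetal-specific allele the fetus actually
carries rise above the cut-off and the rest stay below it; every site
therefore votes for the pathogenic paternal haplotype, matching the
simulated transmission, and the verdict is that invasive confirmation is
needed (the maternal allele, which this assay does not resolve, decides the
final genotype).

Other examples: `examples/select_panel.py` (panel selection over a
660-site synthetic cohort), `examples/spike_sensitivity.py` (two-gDNA
spike mixtures at 1.25–10%), and `examples/study_reanalysis.py` (the
17-family validation summary: sensitivity 88.8%, specificity 98.8%,
8 families avoiding invasive sampling). A thin CLI mirrors the stages:
`niph select-panel`, `niph simulate`, `niph analyze-family`,
`niph evaluate`.

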