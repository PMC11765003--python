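"""Re-derive the validation study's headline statistics from its tables.

Uses the packaged per-replicate call outcomes of the 17-family validation
cohort: rebuilds per-site calls, pools them into confusion counts with
exact binomial confidence intervals, and re-runs the majority-vote
haplotype inference to obtain every family's diagnostic verdict.
"""

from collections import defaultdict

from niph import datasets
from niph.haplotype import combine_replicates, diagnose, infer_inheritance
from niph.performance import confusion_summary

calls = []
per_family = defaultdict(list)
anchors = {}
for row in datasets.call_outcomes().itertuples():
    replicate_calls, haps = datasets.reconstruct_replicate_calls(row)
    calls.extend(replicate_calls)
    r = infer_inheritance(replicate_calls, haps, str(row.family), str(row.replicate))
    per_family[str(row.family)].append(r)
    anchors[str(row.family)] = haps.anchor

s = confusion_summary(calls)
print(f"pooled calls: TP={s.tp} FN={s.fn} TN={s.tn} FP={s.fp} "
      f"({s.concordant}/{s.total} concordant with CVS)")
print(f"sensitivity  {s.sensitivity:5.1f}%  (95% CI {s.ci_sens[0]:.1f}-{s.ci_sens[1]:.1f})")
print(f"specificity  {s.specificity:5.1f}%  (95% CI {s.ci_spec[0]:.2f}-{s.ci_spec[1]:.2f})")

verdicts = defaultdict(list)
for fam, results in per_family.items():
    v = diagnose(combine_replicates(results), fam, anchors[fam]).verdict
    verdicts[v.value].append(fam)
for verdict, fams in sorted(verdicts.items()):
    print(f"{verdict:<22s} {len(fams):>2} families: {', '.join(sorted(fams, key=int))}")
print("(families whose fetus inherited the paternal wild-type haplotype "
      "avoid invasive sampling)")
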