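"""End-to-end per-family analysis: classification to diagnostic verdict.

Stage order per family:

1. classify every panel site by the parental genotype combination;
2. per cfDNA replicate, compute group-ii error rates and the replicate's
   detection cut-off (max + 1 SD);
3. compute the fetal fraction at every informative site and call the
   fetal-specific allele (ff strictly above the cut-off);
4. label calls against the CVS genotype when available;
5. phase the paternal haplotypes (explicit phase > CVS > grandparents) and
   infer the transmitted haplotype by majority vote, per replicate;
6. combine replicates into a family verdict and the diagnostic
   interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .calling import (
    AlleleCall,
    CutoffResult,
    compute_cutoff,
    evaluate_vs_truth,
    make_calls,
    replicate_error_rates,
)
from .classify import (
    SNVClassification,
    SNVGroup,
    classify_family,
    group_counts,
    pq_allele_map,
)
from .config import RunConfig
from .core import FamilyRecord, orient_depths
from .haplotype import (
    DiagnosticResult,
    Inherited,
    InheritanceResult,
    PaternalHaplotypes,
    combine_replicates,
    diagnose,
    infer_inheritance,
    phase_father_from_cvs,
    phase_father_from_grandparents,
)
from .performance import PerformanceSummary, confusion_summary

logger = logging.getLogger(__name__)


@dataclass
class ReplicateAnalysis:
    replicate_id: str
    cutoff: CutoffResult
    calls: list[AlleleCall]
    inheritance: InheritanceResult


@dataclass
class FamilyAnalysis:
    family: FamilyRecord
    classifications: list[SNVClassification]
    haplotypes: Optional[PaternalHaplotypes]
    replicates: list[ReplicateAnalysis] = field(default_factory=list)
    family_inherited: Inherited = Inherited.NOT_APPLICABLE
    diagnostic: Optional[DiagnosticResult] = None

    @property
    def n_informative(self) -> int:
        return sum(
            1 for c in self.classifications if c.group is SNVGroup.I_INFORMATIVE
        )

    @property
    def group_counts(self):
        return group_counts(self.classifications)

    def labelled_calls(self) -> list[AlleleCall]:
        return [c for r in self.replicates for c in r.calls]

    def confusion(self) -> Optional[PerformanceSummary]:
        calls = [c for c in self.labelled_calls() if c.label.value != "no_truth"]
        if not calls:
            return None
        return confusion_summary(calls)


def resolve_phase(
    family: FamilyRecord, phase: Optional[PaternalHaplotypes] = None
) -> PaternalHaplotypes:
    """Pick the paternal phase source: explicit > CVS > grandparents."""
    if phase is not None:
        return phase
    errors = []
    if family.cvs is not None:
        try:
            return phase_father_from_cvs(family)
        except ValueError as e:
            errors.append(str(e))
    if family.grandparents:
        try:
            return phase_father_from_grandparents(family)
        except ValueError as e:
            errors.append(str(e))
    raise ValueError(
        f"family {family.family_id}: paternal phase unavailable "
        f"(no external phase, and {'; '.join(errors) if errors else 'no CVS or grandparental genotypes'})"
    )


def analyze_family(
    family: FamilyRecord,
    config: RunConfig = RunConfig(),
    phase: Optional[PaternalHaplotypes] = None,
) -> FamilyAnalysis:
    """Run the full cfDNA analysis for one family."""
    if not family.cfdna_replicates:
        raise ValueError(f"family {family.family_id}: no cfDNA replicates")
    classifications = classify_family(family)
    counts = group_counts(classifications)
    logger.info(
        "family %s: %s",
        family.family_id,
        ", ".join(f"{g.value}={n}" for g, n in counts.items() if n),
    )
    pq = pq_allele_map(classifications, family.mother)

    n_informative = counts[SNVGroup.I_INFORMATIVE]
    haplotypes: Optional[PaternalHaplotypes] = None
    if n_informative > 0:
        haplotypes = resolve_phase(family, phase)

    replicates: list[ReplicateAnalysis] = []
    for rep_id, raw in family.cfdna_replicates:
        oriented = {
            k: orient_depths(d, pq[k]) for k, d in raw.items() if k in pq
        }
        rates = replicate_error_rates(classifications, oriented)
        cutoff = compute_cutoff(
            rates, replicate_id=rep_id, sd_multiplier=config.cutoff_sd_multiplier
        )
        calls = make_calls(classifications, oriented, cutoff, rep_id)
        if family.cvs is not None:
            calls = evaluate_vs_truth(calls, family.cvs)
        if haplotypes is not None:
            inh = infer_inheritance(
                calls,
                haplotypes,
                family_id=family.family_id,
                replicate_id=rep_id,
                majority_threshold=config.majority_threshold,
            )
            if 0 < inh.n_informative < config.min_informative:
                inh = InheritanceResult(
                    family.family_id, rep_id, Inherited.INCONCLUSIVE,
                    inh.n_support, inh.n_informative,
                )
        else:
            inh = InheritanceResult(
                family.family_id, rep_id, Inherited.NOT_APPLICABLE, 0, 0
            )
        replicates.append(ReplicateAnalysis(rep_id, cutoff, calls, inh))

    family_inherited = combine_replicates([r.inheritance for r in replicates])
    anchor = haplotypes.anchor if haplotypes is not None else "hap_path"
    diagnostic = diagnose(family_inherited, family.family_id, anchor=anchor)
    return FamilyAnalysis(
        family=family,
        classifications=classifications,
        haplotypes=haplotypes,
        replicates=replicates,
        family_inherited=family_inherited,
        diagnostic=diagnostic,
    )
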