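"""Fetal-fraction computation, cut-off calibration, and fetal-allele calling.

The central statistic is the per-site fetal fraction

    ff(%) = 2 p / (p + q) * 100

where ``p`` is the read count of the fetal-specific allele and ``q`` the
count of the allele shared by mother and fetus.  The factor 2 reflects that
a heterozygous fetus contributes the fetal-specific allele on only one of
its two chromosomes: if the fetal DNA fraction in the plasma is f, the
expected share of fetal-specific reads is f/2, and ff estimates f.

The same formula applied at group-ii sites (both parents homozygous for the
same allele, so the other allele cannot legitimately occur) measures the
per-site error rate.  Each cfDNA replicate is calibrated on its own: the
detection cut-off is the maximum group-ii error rate plus one standard
deviation of those error rates.  A site is called positive (fetal-specific
allele present) when its ff strictly exceeds the replicate's cut-off.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Optional

from .classify import SNVClassification, SNVGroup
from .core import AlleleDepths, Genotype, GenotypeMap, SNVSite


def fetal_fraction(p: int, q: int) -> float:
    """ff(%) = 2p/(p+q)*100; requires p+q > 0."""
    if p < 0 or q < 0:
        raise ValueError("read counts must be non-negative")
    if p + q == 0:
        raise ValueError("fetal fraction undefined at zero depth")
    return 200.0 * p / (p + q)


def error_rate(depths: AlleleDepths) -> float:
    """Error rate (%) at a group-ii site: ff applied to the unexpected allele.

    ``depths.p`` must count the panel allele carried by neither parent and
    ``depths.q`` the shared parental allele.
    """
    return fetal_fraction(depths.p, depths.q)


@dataclass(frozen=True)
class CutoffResult:
    """Per-replicate error-rate summary and the detection cut-off."""

    replicate_id: str
    max_error: float  # percent
    sd_error: float  # percent, sample SD (n-1)
    sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.max_error < 0 or self.sd_error < 0:
            raise ValueError("error-rate summaries must be non-negative")

    @property
    def cutoff(self) -> float:
        return self.max_error + self.sd_multiplier * self.sd_error


def compute_cutoff(
    error_rates: list[float], replicate_id: str = "", sd_multiplier: float = 1.0
) -> CutoffResult:
    """Cut-off = max(error rates) + ``sd_multiplier`` * sample SD.

    Calibrated within one cfDNA replicate over its group-ii sites; replicates
    are never pooled.  Needs at least two values for the SD.
    """
    if len(error_rates) < 2:
        raise ValueError(
            "cut-off calibration needs >= 2 group-ii error rates; "
            "supply more group-ii sites or configure an external cut-off"
        )
    return CutoffResult(
        replicate_id=replicate_id,
        max_error=max(error_rates),
        sd_error=statistics.stdev(error_rates),
        sd_multiplier=sd_multiplier,
    )


class Call(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Truth(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class CallLabel(enum.Enum):
    TP = "TP"
    FN = "FN"
    TN = "TN"
    FP = "FP"
    NO_TRUTH = "no_truth"


def call_allele(ff: float, cutoff: float) -> Call:
    """Positive iff ff strictly exceeds the cut-off."""
    return Call.POSITIVE if ff > cutoff else Call.NEGATIVE


@dataclass(frozen=True)
class AlleleCall:
    """One informative-site decision in one cfDNA replicate."""

    site: SNVSite
    replicate_id: str
    fetal_specific_allele: str
    p: int
    q: int
    ff: float
    cutoff: float
    call: Call
    truth: Truth = Truth.UNKNOWN
    label: CallLabel = CallLabel.NO_TRUTH


def make_calls(
    classifications: list[SNVClassification],
    depths: dict[str, AlleleDepths],
    cutoff: CutoffResult,
    replicate_id: str,
) -> list[AlleleCall]:
    """Call the fetal-specific allele at every group-i (and pathogenic group-i)
    site with depth data.

    ``depths`` is keyed by site key, with ``p`` already assigned to the
    fetal-specific allele (see :func:`niph.io.read_allele_depths`).
    """
    calls = []
    for cls in classifications:
        if cls.group is not SNVGroup.I_INFORMATIVE:
            continue
        d = depths.get(cls.site.key)
        if d is None or d.depth == 0:
            continue
        ff = fetal_fraction(d.p, d.q)
        calls.append(
            AlleleCall(
                site=cls.site,
                replicate_id=replicate_id,
                fetal_specific_allele=cls.fetal_specific_allele,
                p=d.p,
                q=d.q,
                ff=ff,
                cutoff=cutoff.cutoff,
                call=call_allele(ff, cutoff.cutoff),
            )
        )
    return calls


def replicate_error_rates(
    classifications: list[SNVClassification],
    depths: dict[str, AlleleDepths],
) -> list[float]:
    """Error rates at the group-ii sites of one replicate.

    At a group-ii site both parents are homozygous for one panel allele; the
    unexpected allele is the other panel allele.  ``depths`` entries must
    carry the unexpected-allele count in ``p`` (io handles the orientation).
    """
    rates = []
    for cls in classifications:
        if cls.group is not SNVGroup.II_CUTOFF:
            continue
        d = depths.get(cls.site.key)
        if d is None or d.depth == 0:
            continue
        rates.append(error_rate(d))
    return rates


def evaluate_vs_truth(calls: list[AlleleCall], cvs: GenotypeMap) -> list[AlleleCall]:
    """Label calls against the CVS (invasive fetal sample) genotypes.

    Truth is *present* when the CVS carries the fetal-specific allele.
    Labels: TP = present & positive, FN = present & negative,
    TN = absent & negative, FP = absent & positive.  Sites without a CVS
    genotype get ``no_truth`` and are excluded from confusion counts.
    """
    labelled = []
    for c in calls:
        gt = cvs.get(c.site.key, Genotype.MISSING)
        carries = gt.carries(c.fetal_specific_allele, c.site)
        if carries is None:
            truth, label = Truth.UNKNOWN, CallLabel.NO_TRUTH
        elif carries:
            truth = Truth.PRESENT
            label = CallLabel.TP if c.call is Call.POSITIVE else CallLabel.FN
        else:
            truth = Truth.ABSENT
            label = CallLabel.FP if c.call is Call.POSITIVE else CallLabel.TN
        labelled.append(
            AlleleCall(
                site=c.site,
                replicate_id=c.replicate_id,
                fetal_specific_allele=c.fetal_specific_allele,
                p=c.p,
                q=c.q,
                ff=c.ff,
                cutoff=c.cutoff,
                call=c.call,
                truth=truth,
                label=label,
            )
        )
    return labelled
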