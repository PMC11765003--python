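"""Paternal haplotype phasing, inheritance inference, and diagnosis.

The informative SNVs tell us, site by site, whether the fetus inherited the
paternal allele absent from the mother.  To turn those per-site calls into a
clinical statement, the father's alleles must first be *phased* — assigned
to his two physical haplotypes — and the haplotypes anchored to his
wild-type vs pathogenic HBB allele.  Three phase sources are supported,
mirroring clinical practice:

* the CVS fetal genotype (when an invasive sample exists, used for
  validation),
* the father's parents (grandparental trio phasing — the prospective
  clinical route),
* an external phase table from a previous family study.

Each informative-site call then votes: a positive call supports the
haplotype carrying that site's fetal-specific allele, a negative call the
other haplotype.  The transmitted haplotype is the strict majority (> 50%
of votes); an exact tie is inconclusive.  Inheriting the paternal wild-type
haplotype means the fetus cannot be homozygous-affected regardless of the
maternal allele, so invasive sampling is avoided; inheriting the paternal
pathogenic haplotype leaves the fetal status dependent on the (undetermined)
maternal inheritance and invasive confirmation is recommended.

Recombination between the phased sites is neglected: the panel spans the
β-globin gene cluster, short enough that a crossover within one meiosis is
very unlikely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .calling import AlleleCall, Call
from .core import FamilyRecord, Genotype, GenotypeMap, SNVSite, round_half_up

GRANDPARENT_ROLES = (
    "mother_of_mother",
    "father_of_mother",
    "mother_of_father",
    "father_of_father",
)


class PhaseSource(enum.Enum):
    CVS = "cvs"
    GRANDPARENTS = "grandparents"
    EXTERNAL = "external"


@dataclass
class PaternalHaplotypes:
    """The father's two haplotypes over his heterozygous panel sites.

    ``hap_wt`` / ``hap_path`` map site keys to alleles.  ``anchor`` records
    how the pathogenic label was attached: ``"hap_path"`` when the father
    carries a pathogenic variant placed on that haplotype, ``"wt_wt"`` when
    he carries none (both haplotypes wild-type; the labels are then purely
    nominal and any inherited haplotype is non-pathogenic).
    """

    hap_wt: dict[str, str]
    hap_path: dict[str, str]
    anchor: str
    phase_source: PhaseSource
    unphased_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.anchor not in ("hap_path", "wt_wt"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        for k in set(self.hap_wt) & set(self.hap_path):
            if self.hap_wt[k] == self.hap_path[k]:
                raise ValueError(f"haplotypes identical at phased het site {k}")

    def carrier_of(self, site_key: str, allele: str) -> Optional[str]:
        """Which haplotype ('hap_wt'/'hap_path') carries ``allele``; None if unphased."""
        if self.hap_path.get(site_key) == allele:
            return "hap_path"
        if self.hap_wt.get(site_key) == allele:
            return "hap_wt"
        return None


class Inherited(enum.Enum):
    HAP_WT = "hap_wt"
    HAP_PATH = "hap_path"
    INCONCLUSIVE = "inconclusive"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class InheritanceResult:
    family_id: str
    replicate_id: str
    inherited: Inherited
    n_support: int
    n_informative: int

    @property
    def concordance(self) -> Optional[float]:
        """Winner votes / informative votes, percent (None when no votes)."""
        if self.n_informative == 0:
            return None
        return 100.0 * self.n_support / self.n_informative

    @property
    def concordance_rounded(self) -> Optional[float]:
        c = self.concordance
        return None if c is None else round_half_up(c, 0)


class Verdict(enum.Enum):
    INVASIVE_AVOIDED = "invasive_avoided"
    INVASIVE_RECOMMENDED = "invasive_recommended"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class DiagnosticResult:
    family_id: str
    verdict: Verdict
    inherited: Inherited


def _pathogenic_site_keys(family: FamilyRecord) -> set[str]:
    hgvs = {a.hgvs for a in family.father_pathogenic} | {
        a.hgvs for a in family.mother_pathogenic
    }
    return {s.key for s in family.panel if s.id in hgvs}


def _father_pathogenic_het_sites(family: FamilyRecord) -> list[SNVSite]:
    """Panel sites of pathogenic variants where the father is heterozygous."""
    keys = _pathogenic_site_keys(family)
    return [
        s
        for s in family.panel
        if s.key in keys and family.father.get(s.key) is Genotype.HET
    ]


def phase_father_from_cvs(family: FamilyRecord) -> PaternalHaplotypes:
    """Phase the father using the CVS fetal genotype.

    At each site where the father is heterozygous and the mother homozygous,
    the paternal allele transmitted to the fetus is the CVS allele not
    attributable to the mother.  The transmitted alleles form one haplotype
    and the untransmitted alleles the other; the pair is anchored by whether
    the paternal pathogenic variant was transmitted.
    """
    if family.cvs is None:
        raise ValueError(
            f"family {family.family_id}: no CVS genotypes; "
            "use grandparental or external phasing"
        )
    transmitted: dict[str, str] = {}
    untransmitted: dict[str, str] = {}
    for site in family.panel:
        k = site.key
        if family.father.get(k) is not Genotype.HET:
            continue
        m = family.mother.get(k, Genotype.MISSING)
        c = family.cvs.get(k, Genotype.MISSING)
        if not m.is_hom or c is Genotype.MISSING:
            continue
        maternal_allele = site.ref_allele if m is Genotype.HOM_REF else site.alt_allele
        other = site.alt_allele if m is Genotype.HOM_REF else site.ref_allele
        # fetus = maternal allele + paternal transmitted allele
        if c is Genotype.HET:
            t = other
        elif (c is Genotype.HOM_REF) == (m is Genotype.HOM_REF):
            t = maternal_allele
        else:  # CVS homozygous for the allele the mother lacks: non-Mendelian
            raise ValueError(
                f"family {family.family_id}: CVS {c.value} at {k} impossible "
                f"given mother {m.value}"
            )
        transmitted[k] = t
        untransmitted[k] = site.alt_allele if t == site.ref_allele else site.ref_allele
    if not transmitted:
        raise ValueError(
            f"family {family.family_id}: no phaseable paternal het sites from CVS"
        )
    path_sites = _father_pathogenic_het_sites(family)
    if not path_sites:
        return PaternalHaplotypes(
            hap_wt=transmitted, hap_path=untransmitted, anchor="wt_wt",
            phase_source=PhaseSource.CVS,
        )
    # was the paternal pathogenic allele transmitted?
    transmitted_is_path = None
    for s in path_sites:
        k = s.key
        c = family.cvs.get(k, Genotype.MISSING)
        m = family.mother.get(k, Genotype.MISSING)
        if k in transmitted:  # mother homozygous there: already resolved
            transmitted_is_path = transmitted[k] == s.alt_allele
            break
        if c.is_hom:
            # fetus homozygous: the paternal transmitted allele is unambiguous
            transmitted_is_path = c is Genotype.HOM_ALT
            break
        if m is Genotype.HOM_REF and c is Genotype.HET:
            transmitted_is_path = True
            break
    if transmitted_is_path is None:
        raise ValueError(
            f"family {family.family_id}: cannot anchor haplotypes from CVS "
            "(pathogenic transmission ambiguous); use external phase"
        )
    if transmitted_is_path:
        return PaternalHaplotypes(
            hap_wt=untransmitted, hap_path=transmitted, anchor="hap_path",
            phase_source=PhaseSource.CVS,
        )
    return PaternalHaplotypes(
        hap_wt=transmitted, hap_path=untransmitted, anchor="hap_path",
        phase_source=PhaseSource.CVS,
    )


def phase_from_grandparents(
    parent: GenotypeMap,
    grandfather: GenotypeMap,
    grandmother: GenotypeMap,
    panel: list[SNVSite],
    pathogenic_site_keys: set[str],
) -> PaternalHaplotypes:
    """Phase a parent through their own parents (trio phasing).

    At each parental heterozygous site the allele origin is assigned when
    Mendelian transmission is unambiguous; sites where both assignments are
    feasible remain unphased and are excluded from voting.  The haplotype
    pair is anchored by which grandparent contributed the pathogenic allele.
    """
    from_gf: dict[str, str] = {}
    from_gm: dict[str, str] = {}
    unphased: list[str] = []
    for site in panel:
        k = site.key
        if parent.get(k) is not Genotype.HET:
            continue
        a, b = site.ref_allele, site.alt_allele
        gf = grandfather.get(k, Genotype.MISSING)
        gm = grandmother.get(k, Genotype.MISSING)

        def feasible(x: str, y: str) -> bool:
            cx = gf.carries(x, site)
            cy = gm.carries(y, site)
            return (cx is None or cx) and (cy is None or cy)

        opts = [(x, y) for x, y in ((a, b), (b, a)) if feasible(x, y)]
        if not opts:
            raise ValueError(
                f"Mendelian inconsistency at {k}: parent allele absent from "
                "both grandparents"
            )
        if len(opts) == 2:
            unphased.append(k)
            continue
        x, y = opts[0]
        from_gf[k] = x
        from_gm[k] = y
    # anchor: locate the pathogenic variant's grandparental origin
    anchor_origin = None
    for k in pathogenic_site_keys:
        if k in from_gf:
            site = next(s for s in panel if s.key == k)
            if from_gf[k] == site.alt_allele:
                anchor_origin = "gf"
            else:
                anchor_origin = "gm"
            break
    if anchor_origin is None:
        if any(k in pathogenic_site_keys for k in unphased):
            raise ValueError(
                "pathogenic variant unphased in grandparental analysis; "
                "cannot anchor haplotypes"
            )
        return PaternalHaplotypes(
            hap_wt=from_gf, hap_path=from_gm, anchor="wt_wt",
            phase_source=PhaseSource.GRANDPARENTS, unphased_sites=unphased,
        )
    if anchor_origin == "gf":
        hap_path, hap_wt = from_gf, from_gm
    else:
        hap_path, hap_wt = from_gm, from_gf
    return PaternalHaplotypes(
        hap_wt=hap_wt, hap_path=hap_path, anchor="hap_path",
        phase_source=PhaseSource.GRANDPARENTS, unphased_sites=unphased,
    )


def phase_father_from_grandparents(family: FamilyRecord) -> PaternalHaplotypes:
    """Convenience wrapper phasing the father via his parents."""
    if not family.grandparents:
        raise ValueError(f"family {family.family_id}: no grandparental genotypes")
    try:
        gf = family.grandparents["father_of_father"]
        gm = family.grandparents["mother_of_father"]
    except KeyError as e:
        raise ValueError(
            f"family {family.family_id}: missing grandparental role {e}"
        ) from None
    return phase_from_grandparents(
        family.father, gf, gm, family.panel, _pathogenic_site_keys(family)
    )


def infer_inheritance(
    calls: list[AlleleCall],
    haplotypes: PaternalHaplotypes,
    family_id: str = "",
    replicate_id: str = "",
    majority_threshold: float = 50.0,
) -> InheritanceResult:
    """Majority vote of informative-site calls over the paternal haplotypes.

    A positive call (fetal-specific allele detected) votes for the haplotype
    carrying that allele; a negative call votes for the other haplotype.
    The winner needs a strict majority (> ``majority_threshold`` percent of
    votes).  Unphased sites are excluded.  No votes -> not applicable; an
    exact tie -> inconclusive.
    """
    votes = {"hap_wt": 0, "hap_path": 0}
    for c in calls:
        carrier = haplotypes.carrier_of(c.site.key, c.fetal_specific_allele)
        if carrier is None:
            continue
        other = "hap_wt" if carrier == "hap_path" else "hap_path"
        votes[carrier if c.call is Call.POSITIVE else other] += 1
    n = votes["hap_wt"] + votes["hap_path"]
    if n == 0:
        return InheritanceResult(family_id, replicate_id, Inherited.NOT_APPLICABLE, 0, 0)
    winner = max(votes, key=votes.get)
    share = 100.0 * votes[winner] / n
    if share > majority_threshold:
        inherited = Inherited.HAP_WT if winner == "hap_wt" else Inherited.HAP_PATH
        return InheritanceResult(family_id, replicate_id, inherited, votes[winner], n)
    return InheritanceResult(
        family_id, replicate_id, Inherited.INCONCLUSIVE, votes[winner], n
    )


def combine_replicates(results: list[InheritanceResult]) -> Inherited:
    """Family-level inheritance across cfDNA replicates.

    Replicates that agree on the winning haplotype give that haplotype;
    disagreement is inconclusive.  Replicates with no informative sites are
    ignored unless all are empty (then not applicable).
    """
    decided = [
        r.inherited for r in results if r.inherited in (Inherited.HAP_WT, Inherited.HAP_PATH)
    ]
    if not decided:
        if any(r.inherited is Inherited.INCONCLUSIVE for r in results):
            return Inherited.INCONCLUSIVE
        return Inherited.NOT_APPLICABLE
    if len(set(decided)) == 1:
        return decided[0]
    return Inherited.INCONCLUSIVE


def diagnose(
    inherited: Inherited, family_id: str = "", anchor: str = "hap_path"
) -> DiagnosticResult:
    """Clinical interpretation of the inherited paternal haplotype.

    Wild-type haplotype inherited -> the fetus is at most a carrier through
    the mother, so invasive sampling is avoided.  Pathogenic haplotype
    inherited -> the fetal status depends on the maternal allele, so invasive
    confirmation is recommended.  When the father carries no pathogenic
    variant (``anchor='wt_wt'``) any determinate inheritance is benign.
    """
    if inherited in (Inherited.INCONCLUSIVE, Inherited.NOT_APPLICABLE):
        verdict = Verdict.NOT_APPLICABLE
    elif anchor == "wt_wt":
        verdict = Verdict.INVASIVE_AVOIDED
    elif inherited is Inherited.HAP_WT:
        verdict = Verdict.INVASIVE_AVOIDED
    else:
        verdict = Verdict.INVASIVE_RECOMMENDED
    return DiagnosticResult(family_id, verdict, inherited)
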