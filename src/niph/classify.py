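"""Per-family classification of panel SNVs by parental genotype combination.

Four combinations matter for cfDNA analysis of the paternal inheritance:

* group i   (*informative*): mother homozygous, father heterozygous.  One
  paternal allele is absent from the maternal genome; reads of that
  fetal-specific allele in maternal plasma are evidence the fetus inherited
  it.
* group ii  (*cut-off*): both parents homozygous for the same allele.  Any
  read of the other allele is biologically impossible from this family, so
  these sites measure the assay's error rate and calibrate the detection
  cut-off.
* group iii (*fetal presence*): parents homozygous for different alleles;
  the paternal allele is always fetal-specific and its presence confirms
  fetal DNA in the plasma.  Classified and reported, but generates no calls
  by default.
* group iv  (*maternal het*): mother heterozygous.  No fetal-specific allele
  exists; resolving these requires dosage methods out of scope here, so the
  sites are excluded from calling.

A site with any missing parental genotype is unusable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .core import FamilyRecord, Genotype, SNVSite


class SNVGroup(enum.Enum):
    I_INFORMATIVE = "i_informative"
    II_CUTOFF = "ii_cutoff"
    III_FETAL_PRESENCE = "iii_fetal_presence"
    IV_MATERNAL_HET = "iv_maternal_het"
    UNUSABLE = "unusable"


@dataclass(frozen=True)
class SNVClassification:
    site: SNVSite
    group: SNVGroup
    fetal_specific_allele: Optional[str]  # set for groups i and iii

    @property
    def shared_allele(self) -> Optional[str]:
        """The allele common to mother and fetus (the ``q`` allele)."""
        if self.fetal_specific_allele is None:
            return None
        if self.fetal_specific_allele == self.site.ref_allele:
            return self.site.alt_allele
        return self.site.ref_allele


def classify_snv(mother_gt: Genotype, father_gt: Genotype, site: SNVSite) -> SNVClassification:
    """Assign one panel site to its parental-genotype group."""
    if Genotype.MISSING in (mother_gt, father_gt):
        return SNVClassification(site, SNVGroup.UNUSABLE, None)
    if mother_gt is Genotype.HET:
        return SNVClassification(site, SNVGroup.IV_MATERNAL_HET, None)
    # mother homozygous from here on; her absent allele:
    maternal_absent = (
        site.alt_allele if mother_gt is Genotype.HOM_REF else site.ref_allele
    )
    if father_gt is Genotype.HET:
        return SNVClassification(site, SNVGroup.I_INFORMATIVE, maternal_absent)
    if father_gt is mother_gt:
        return SNVClassification(site, SNVGroup.II_CUTOFF, None)
    # both homozygous, different alleles: the paternal allele is fetal-specific
    return SNVClassification(site, SNVGroup.III_FETAL_PRESENCE, maternal_absent)


def classify_family(family: FamilyRecord) -> list[SNVClassification]:
    """Classify every panel site of a family, ordered by genomic position."""
    out = []
    for site in sorted(family.panel):
        m = family.mother.get(site.key, Genotype.MISSING)
        f = family.father.get(site.key, Genotype.MISSING)
        out.append(classify_snv(m, f, site))
    return out


def informative_snvs(family: FamilyRecord) -> list[SNVClassification]:
    """Group-i sites of a family (mother homozygous, father heterozygous)."""
    return [c for c in classify_family(family) if c.group is SNVGroup.I_INFORMATIVE]


def cutoff_snvs(family: FamilyRecord) -> list[SNVClassification]:
    """Group-ii sites of a family (both parents homozygous, same allele)."""
    return [c for c in classify_family(family) if c.group is SNVGroup.II_CUTOFF]


def pq_allele_map(
    classifications: list[SNVClassification], mother: dict
) -> dict[str, str]:
    """Which allele plays the ``p`` role at each usable site.

    Group i / iii: the fetal-specific allele.  Group ii: the panel allele
    carried by neither parent (its reads measure the error rate).  Groups iv
    and unusable sites are omitted.
    """
    out: dict[str, str] = {}
    for c in classifications:
        if c.group in (SNVGroup.I_INFORMATIVE, SNVGroup.III_FETAL_PRESENCE):
            out[c.site.key] = c.fetal_specific_allele
        elif c.group is SNVGroup.II_CUTOFF:
            m = mother[c.site.key]
            out[c.site.key] = (
                c.site.alt_allele if m is Genotype.HOM_REF else c.site.ref_allele
            )
    return out


def group_counts(classifications: list[SNVClassification]) -> dict[SNVGroup, int]:
    counts = {g: 0 for g in SNVGroup}
    for c in classifications:
        counts[c.group] += 1
    return counts
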