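"""Shared domain types for the NIPH (non-invasive prenatal haplotyping) pipeline.

The pipeline works downstream of read alignment and variant calling: its
inputs are genotypes (parents, CVS, optionally grandparents) and per-site
allele read depths from cell-free DNA (cfDNA) sequenced at high coverage.
All sites are biallelic SNVs; indels and multiallelic records are rejected
at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SNVSite:
    """A biallelic SNV locus, 1-based coordinates on the forward strand.

    ``ref_allele``/``alt_allele`` are single bases for genomic SNVs.  HGVS-
    named pathogenic variants are carried through the same type with the
    wild-type allele as ``ref_allele`` and the pathogenic allele as
    ``alt_allele``; their ``id`` holds the HGVS string.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles must differ at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> str:
        """Stable string key, e.g. ``'11:5227002:C:T'``."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    def swapped(self) -> "SNVSite":
        """The same locus with ref/alt labels exchanged."""
        return SNVSite(self.chrom, self.pos, self.alt_allele, self.ref_allele, self.id)


class Genotype(enum.Enum):
    """Diploid genotype state at a biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def alt_count(self) -> Optional[int]:
        """Copies of the alt allele (0/1/2), or None when missing."""
        return {
            Genotype.HOM_REF: 0,
            Genotype.HET: 1,
            Genotype.HOM_ALT: 2,
            Genotype.MISSING: None,
        }[self]

    @property
    def is_hom(self) -> bool:
        return self in (Genotype.HOM_REF, Genotype.HOM_ALT)

    def carries(self, allele: str, site: SNVSite) -> Optional[bool]:
        """Whether this genotype carries ``allele`` at ``site`` (None if missing)."""
        if self is Genotype.MISSING:
            return None
        if allele == site.ref_allele:
            return self in (Genotype.HOM_REF, Genotype.HET)
        if allele == site.alt_allele:
            return self in (Genotype.HOM_ALT, Genotype.HET)
        return False

    def swapped(self) -> "Genotype":
        """Genotype under a ref/alt label swap."""
        return {
            Genotype.HOM_REF: Genotype.HOM_ALT,
            Genotype.HOM_ALT: Genotype.HOM_REF,
        }.get(self, self)


# integer codes used by the cohort matrix
GT_CODE = {
    Genotype.HOM_REF: 0,
    Genotype.HET: 1,
    Genotype.HOM_ALT: 2,
    Genotype.MISSING: -1,
}
CODE_GT = {v: k for k, v in GT_CODE.items()}


@dataclass
class CohortGenotypes:
    """Site x individual genotype matrix for panel selection.

    ``calls`` is an int matrix of shape (n_sites, n_individuals) with codes
    0=hom_ref, 1=het, 2=hom_alt, -1=missing.
    """

    sites: list[SNVSite]
    individuals: list[str]
    calls: "object"  # numpy int array, (n_sites, n_individuals)

    def __post_init__(self) -> None:
        import numpy as np

        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        if not set(map(int, set(self.calls.ravel().tolist()))) <= {-1, 0, 1, 2}:
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


@dataclass(frozen=True)
class AlleleDepths:
    """Read counts at one site of one cfDNA replicate (or spike mixture).

    ``p`` counts reads of the fetal-specific (or minor/unexpected) allele,
    ``q`` reads of the other, shared allele.  Which physical base plays the
    role of ``p`` is decided upstream by the per-family SNV classification.
    """

    site: SNVSite
    p: int
    q: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError(f"negative read count at {self.site.key}: p={self.p} q={self.q}")

    @property
    def depth(self) -> int:
        return self.p + self.q


@dataclass(frozen=True)
class SiteDepths:
    """Raw ref/alt read counts at one site, before p/q orientation.

    Which allele plays the fetal-specific role ``p`` depends on the family's
    parental genotypes, so raw tables keep ref/alt counts and orientation is
    applied per family (see :func:`orient_depths`).
    """

    site: SNVSite
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(f"negative read count at {self.site.key}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


def orient_depths(raw: SiteDepths, p_allele: str) -> AlleleDepths:
    """Assign p to the reads of ``p_allele`` and q to the other panel allele.

    Involutive under swapping ref/alt labels together with ``p_allele``.
    """
    if p_allele == raw.site.ref_allele:
        return AlleleDepths(raw.site, p=raw.ref_count, q=raw.alt_count)
    if p_allele == raw.site.alt_allele:
        return AlleleDepths(raw.site, p=raw.alt_count, q=raw.ref_count)
    raise ValueError(f"{p_allele!r} is not an allele of {raw.site.key}")


class CarrierState(enum.Enum):
    HET = "het"
    HOM = "hom"
    ABSENT = "absent"


@dataclass(frozen=True)
class PathogenicAnnotation:
    """An HGVS-named pathogenic variant and the carrier state of one person."""

    hgvs: str
    carrier_state: CarrierState

    @property
    def genotype(self) -> Genotype:
        return {
            CarrierState.ABSENT: Genotype.HOM_REF,
            CarrierState.HET: Genotype.HET,
            CarrierState.HOM: Genotype.HOM_ALT,
        }[self.carrier_state]


GenotypeMap = dict[str, Genotype]  # keyed by SNVSite.key


@dataclass
class FamilyRecord:
    """One at-risk family: parental genotypes, cfDNA replicates, optional truth.

    All genotype maps are keyed by :attr:`SNVSite.key` over the same panel.
    ``cvs`` (chorionic villus sample) is the invasive fetal genotype used as
    ground truth and, where available, for paternal phasing.  ``grandparents``
    maps the four roles ``mother_of_mother`` / ``father_of_mother`` /
    ``mother_of_father`` / ``father_of_father`` to genotype maps.
    """

    family_id: str
    panel: list[SNVSite]
    mother: GenotypeMap
    father: GenotypeMap
    cvs: Optional[GenotypeMap] = None
    grandparents: Optional[dict[str, GenotypeMap]] = None
    cfdna_replicates: list[tuple[str, dict[str, SiteDepths]]] = field(default_factory=list)
    mother_pathogenic: list[PathogenicAnnotation] = field(default_factory=list)
    father_pathogenic: list[PathogenicAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = {s.key for s in self.panel}
        for name, gmap in (("mother", self.mother), ("father", self.father)):
            extra = set(gmap) - keys
            if extra:
                raise ValueError(f"{name} genotypes at sites absent from panel: {sorted(extra)[:3]}")
        if self.cvs is not None:
            self._check_mendelian()

    def _check_mendelian(self) -> None:
        """CVS genotypes must be producible from the parents at non-missing sites."""
        for site in self.panel:
            k = site.key
            m = self.mother.get(k, Genotype.MISSING)
            f = self.father.get(k, Genotype.MISSING)
            c = self.cvs.get(k, Genotype.MISSING)
            if Genotype.MISSING in (m, f, c):
                continue
            allowed = {
                (ma + fa)
                for ma in _gamete_counts(m)
                for fa in _gamete_counts(f)
            }
            if c.alt_count not in allowed:
                raise ValueError(
                    f"family {self.family_id}: CVS genotype {c.value} at {k} "
                    f"inconsistent with parents ({m.value} x {f.value})"
                )

    def site_by_key(self, key: str) -> SNVSite:
        for s in self.panel:
            if s.key == key:
                return s
        raise KeyError(key)


def _gamete_counts(gt: Genotype) -> tuple[int, ...]:
    """Possible alt-allele doses a parent with ``gt`` can transmit."""
    return {
        Genotype.HOM_REF: (0,),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1,),
    }[gt]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching how the study tables print.

    Python's built-in ``round`` is banker's rounding; report tables here use
    conventional half-up rounding (e.g. 63.6 -> 64 at integer precision).
    """
    import decimal

    d = decimal.Decimal(repr(x)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)
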