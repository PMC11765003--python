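"""Synthetic data generators for every pipeline input.

No raw sequencing data accompanies the validation study this pipeline
re-implements, so these generators produce statistically matched stand-ins:

* a population cohort genotyped at β-globin-cluster SNVs, drawn from
  Hardy-Weinberg proportions per site (with an optional fixed composition
  of common / artefactual / HWE-violating / conforming sites shaped like the
  study's 660-site screen);
* at-risk family trios — parental haplotypes, Mendelian fetal genotype, CVS
  truth, optional grandparents — with cfDNA allele read counts at each panel
  site drawn from the fetomaternal mixture model;
* two-gDNA spike mixtures at a known minority ratio.

The cfDNA read model: total reads per site are Poisson with mean ``depth``
(negative-binomial overdispersion optional); each read derives from the
mother with probability 1−f and the fetus with probability f (f = fetal
fraction, defaulting into the 3–20% range typical of maternal plasma);
the read's allele follows the contributor's genotype and is flipped to the
other panel allele with probability ``error``.  Under this model the
expected per-site fetal fraction statistic 2p/(p+q) recovers f at
informative sites, and the expected group-ii error rate is 2·error.

Defaults: depth 10 000 (the assay's coverage target), error 0.003 (chosen so
simulated group-ii error-rate maxima span the 0.2–1.7% range observed in
calibration replicates), fetal fraction 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    CohortGenotypes,
    FamilyRecord,
    Genotype,
    PathogenicAnnotation,
    CarrierState,
    SiteDepths,
    SNVSite,
    AlleleDepths,
)
from .haplotype import PaternalHaplotypes, PhaseSource

_CHROM = "11"
_BASE_POS = 5_200_000  # β-globin cluster neighbourhood, arbitrary synthetic grid


@dataclass
class SimConfig:
    """Shared knobs for the family/cohort simulators."""

    n_sites: int = 150
    allele_freqs: Union[float, Sequence[float]] = 0.5
    n_individuals: int = 96
    fetal_fraction: float = 0.10
    depth: float = 10_000.0
    error: float = 0.003
    overdispersion: Optional[float] = None  # NB shape k; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = self.freq_array()
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal fraction must lie in [0, 1]")
        if not 0.0 <= self.error <= 0.5:
            raise ValueError("per-read error must lie in [0, 0.5]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def freq_array(self) -> np.ndarray:
        if np.isscalar(self.allele_freqs):
            return np.full(self.n_sites, float(self.allele_freqs))
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(freqs) != self.n_sites:
            raise ValueError("allele_freqs length must equal n_sites")
        return freqs


@dataclass
class SpikeConfig:
    """Two-gDNA mixture: ``spike_fraction`` of the minor sample in the blend."""

    spike_fraction: float = 0.10
    n_sites: int = 67
    depth: float = 10_000.0
    error: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike fraction must lie in [0, 1]")


def _make_panel(n_sites: int, tag: str = "snv") -> list[SNVSite]:
    bases = ("A", "C", "G", "T")
    sites = []
    for i in range(n_sites):
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        sites.append(SNVSite(_CHROM, _BASE_POS + 997 * (i + 1), ref, alt, f"{tag}{i + 1}"))
    return sites


def _draw_total_reads(rng: np.random.Generator, depth: float,
                      overdispersion: Optional[float], size: int) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(depth, size=size)
    k = overdispersion
    lam = rng.gamma(shape=k, scale=depth / k, size=size)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> CohortGenotypes:
    """Cohort genotypes drawn from HWE proportions at each site's frequency."""
    rng = np.random.default_rng(config.seed)
    freqs = config.freq_array()
    sites = _make_panel(config.n_sites)
    probs = np.stack(
        [(1 - freqs) ** 2, 2 * freqs * (1 - freqs), freqs**2], axis=1
    )
    calls = np.empty((config.n_sites, config.n_individuals), dtype=np.int8)
    for i in range(config.n_sites):
        calls[i] = rng.choice(3, size=config.n_individuals, p=probs[i])
    individuals = [f"IND{j + 1:03d}" for j in range(config.n_individuals)]
    return CohortGenotypes(sites=sites, individuals=individuals, calls=calls)


def simulate_structured_cohort(
    seed: int = 0,
    n_common: int = 324,
    n_high_het: int = 65,
    n_hwe_fail: int = 52,
    n_conforming: int = 219,
    n_individuals: int = 96,
    het_min: float = 10.0,
    het_max: float = 90.0,
    hwe_alpha: float = 0.05,
    common_hom_ref_frac: float = 0.95,
) -> CohortGenotypes:
    """Cohort with a fixed composition of site classes.

    Emulates the shape of the population screen that precedes panel design:
    a majority of near-monomorphic *common* sites, a set of heterozygote-
    excess genotyping artefacts, a set of HWE-violating sites inside the
    heterozygosity window, and the conforming sites a selection run should
    retain.  Class membership is guaranteed by construction (each site's
    genotype counts are redrawn until they satisfy the class definition), so
    a panel-selection run over this cohort reports exactly the requested
    status counts under any seed.
    """
    from .panel import hwe_test  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n = n_individuals
    count_triples: list[tuple[int, int, int]] = []

    max_offref = int(np.floor(n * (1 - common_hom_ref_frac)))  # strict > frac
    if n * (1 - common_hom_ref_frac) == max_offref:
        max_offref -= 1
    for _ in range(n_common):
        n_het = int(rng.integers(0, max_offref + 1))
        count_triples.append((n - n_het, n_het, 0))

    min_het_hi = int(np.ceil(n * het_max / 100.0))
    if n * het_max / 100.0 == min_het_hi:
        min_het_hi += 1  # strict > het_max
    for _ in range(n_high_het):
        n_het = int(rng.integers(min_het_hi, n + 1))
        rest = n - n_het
        n2 = int(rng.integers(0, rest + 1))
        count_triples.append((rest - n2, n_het, n2))

    lo = int(np.ceil(n * het_min / 100.0))
    hi = int(np.floor(n * het_max / 100.0))
    for _ in range(n_hwe_fail):
        # heterozygote deficit (inbreeding-like), a classic HWE violation
        while True:
            freq = rng.uniform(0.3, 0.7)
            n_het = int(rng.integers(lo, max(lo + 1, int(0.4 * hi))))
            n_alt_total = int(round(2 * n * freq))
            n2 = (n_alt_total - n_het) // 2
            n0 = n - n_het - n2
            if n0 < 0 or n2 < 0:
                continue
            if not lo <= n_het <= hi:
                continue
            if n0 / n > common_hom_ref_frac:
                continue
            if hwe_test(n0, n_het, n2) <= hwe_alpha:
                count_triples.append((n0, n_het, n2))
                break

    for _ in range(n_conforming):
        while True:
            freq = rng.uniform(0.2, 0.8)
            g = rng.choice(3, size=n, p=[(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
            n0, n_het, n2 = int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
            if not lo <= n_het <= hi:
                continue
            if n0 / n > common_hom_ref_frac:
                continue
            if hwe_test(n0, n_het, n2) > hwe_alpha:
                count_triples.append((n0, n_het, n2))
                break

    n_sites = len(count_triples)
    sites = _make_panel(n_sites)
    calls = np.empty((n_sites, n), dtype=np.int8)
    for i, (n0, n1, n2) in enumerate(count_triples):
        row = np.array([0] * n0 + [1] * n1 + [2] * n2, dtype=np.int8)
        rng.shuffle(row)
        calls[i] = row
    individuals = [f"IND{j + 1:03d}" for j in range(n)]
    return CohortGenotypes(sites=sites, individuals=individuals, calls=calls)


@dataclass
class FamilySimTruth:
    """Ground truth recorded by the family simulator."""

    transmitted_paternal: str  # "wt" or "path"
    father_haplotypes: PaternalHaplotypes
    fetal_genotypes: dict[str, Genotype]


_PATH_HGVS = "NM_000518.5:c.[93-21G>A]"


def simulate_family(
    config: SimConfig,
    family_id: str = "SIM",
    transmitted_paternal: str = "wt",
    n_replicates: int = 1,
    include_grandparents: bool = True,
    include_pathogenic: bool = True,
    mother_counts: Optional[dict[str, Genotype]] = None,
    father_counts: Optional[dict[str, Genotype]] = None,
) -> tuple[FamilyRecord, FamilySimTruth]:
    """Simulate one at-risk family with cfDNA replicates.

    Parental haplotypes are drawn per site from the configured allele
    frequency (or parental genotypes may be supplied); the fetus inherits
    the chosen paternal haplotype (``transmitted_paternal`` in
    ``{"wt", "path"}``) and a random maternal haplotype; the CVS genotype
    map equals the fetal genotype.  When ``include_pathogenic`` is set the
    father is a heterozygous carrier of a pathogenic HBB variant the mother
    does not carry, placed on his ``path`` haplotype, so CVS anchoring and
    direct detection work as in the distinct-variant families.
    """
    if transmitted_paternal not in ("wt", "path"):
        raise ValueError("transmitted_paternal must be 'wt' or 'path'")
    rng = np.random.default_rng(config.seed)
    snv_sites = _make_panel(config.n_sites)
    freqs = config.freq_array()

    def draw_hap() -> np.ndarray:
        return (rng.random(config.n_sites) < freqs).astype(np.int8)

    def haps_from_genotypes(gts: dict[str, Genotype]) -> tuple[np.ndarray, np.ndarray]:
        h1 = np.zeros(config.n_sites, dtype=np.int8)
        h2 = np.zeros(config.n_sites, dtype=np.int8)
        for i, s in enumerate(snv_sites):
            gt = gts[s.key]
            if gt is Genotype.HOM_ALT:
                h1[i] = h2[i] = 1
            elif gt is Genotype.HET:
                which = int(rng.integers(0, 2))
                (h1 if which == 0 else h2)[i] = 1
        return h1, h2

    if mother_counts is None:
        m1, m2 = draw_hap(), draw_hap()
    else:
        m1, m2 = haps_from_genotypes(mother_counts)
    if father_counts is None:
        f_path, f_wt = draw_hap(), draw_hap()
    else:
        f_path, f_wt = haps_from_genotypes(father_counts)

    # pathogenic pseudo-site: wild-type allele G, pathogenic allele A
    path_site = SNVSite(_CHROM, 5_226_774, "G", "A", _PATH_HGVS)
    panel = list(snv_sites)
    if include_pathogenic:
        panel.append(path_site)

    def genotype(a: int, b: int) -> Genotype:
        return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[a + b]

    mother = {s.key: genotype(int(m1[i]), int(m2[i])) for i, s in enumerate(snv_sites)}
    father = {s.key: genotype(int(f_path[i]), int(f_wt[i])) for i, s in enumerate(snv_sites)}
    fet_pat = f_path if transmitted_paternal == "path" else f_wt
    fet_mat = m1 if rng.integers(0, 2) == 0 else m2
    fetus = {s.key: genotype(int(fet_pat[i]), int(fet_mat[i])) for i, s in enumerate(snv_sites)}

    if include_pathogenic:
        mother[path_site.key] = Genotype.HOM_REF
        father[path_site.key] = Genotype.HET  # carrier, variant on the path hap
        fetus[path_site.key] = (
            Genotype.HET if transmitted_paternal == "path" else Genotype.HOM_REF
        )

    # cfDNA replicates
    mat_dose = np.array([mother[s.key].alt_count for s in panel], dtype=float) / 2.0
    fet_dose = np.array([fetus[s.key].alt_count for s in panel], dtype=float) / 2.0
    f = config.fetal_fraction
    base = (1 - f) * mat_dose + f * fet_dose
    p_alt = base * (1 - config.error) + (1 - base) * config.error
    replicates = []
    for r in range(n_replicates):
        totals = _draw_total_reads(rng, config.depth, config.overdispersion, len(panel))
        alts = rng.binomial(totals, p_alt)
        depths = {
            s.key: SiteDepths(s, int(t - a), int(a))
            for s, t, a in zip(panel, totals, alts)
        }
        replicates.append((f"{family_id}_r{r + 1}", depths))

    grandparents = None
    if include_grandparents:
        def gp_pair(h_from_gf: np.ndarray, h_from_gm: np.ndarray):
            gf = {
                s.key: genotype(int(h_from_gf[i]), int(rng.random() < freqs[i]))
                for i, s in enumerate(snv_sites)
            }
            gm = {
                s.key: genotype(int(h_from_gm[i]), int(rng.random() < freqs[i]))
                for i, s in enumerate(snv_sites)
            }
            return gf, gm

        gp_f_gf, gp_f_gm = gp_pair(f_path, f_wt)  # father's path hap from his father
        gp_m_gf, gp_m_gm = gp_pair(m1, m2)
        if include_pathogenic:
            gp_f_gf[path_site.key] = Genotype.HET
            gp_f_gm[path_site.key] = Genotype.HOM_REF
            gp_m_gf[path_site.key] = Genotype.HOM_REF
            gp_m_gm[path_site.key] = Genotype.HOM_REF
        grandparents = {
            "father_of_father": gp_f_gf,
            "mother_of_father": gp_f_gm,
            "father_of_mother": gp_m_gf,
            "mother_of_mother": gp_m_gm,
        }

    annotations = []
    if include_pathogenic:
        annotations = [PathogenicAnnotation(_PATH_HGVS, CarrierState.HET)]
    record = FamilyRecord(
        family_id=family_id,
        panel=panel,
        mother=mother,
        father=father,
        cvs=dict(fetus),
        grandparents=grandparents,
        cfdna_replicates=replicates,
        mother_pathogenic=[],
        father_pathogenic=annotations,
    )
    hap_path = {}
    hap_wt = {}
    for i, s in enumerate(snv_sites):
        if father[s.key] is Genotype.HET:
            hap_path[s.key] = s.alt_allele if f_path[i] else s.ref_allele
            hap_wt[s.key] = s.alt_allele if f_wt[i] else s.ref_allele
    if include_pathogenic:
        hap_path[path_site.key] = path_site.alt_allele
        hap_wt[path_site.key] = path_site.ref_allele
    truth = FamilySimTruth(
        transmitted_paternal=transmitted_paternal,
        father_haplotypes=PaternalHaplotypes(
            hap_wt=hap_wt, hap_path=hap_path, anchor="hap_path",
            phase_source=PhaseSource.EXTERNAL,
        ),
        fetal_genotypes=fetus,
    )
    return record, truth


def simulate_spike(config: SpikeConfig) -> list[AlleleDepths]:
    """Allele depths for a two-gDNA spike mixture at informative sites.

    Informative spike sites have the major (excess) sample homozygous and
    the minor (spiked) sample heterozygous, so the minor-specific allele is
    seen at expected read share s/2 and the fetal-fraction statistic
    2p/(p+q) recovers the spike fraction s in expectation.
    """
    rng = np.random.default_rng(config.seed)
    sites = _make_panel(config.n_sites, tag="spike")
    s = config.spike_fraction
    base = s * 0.5  # minor sample heterozygous, major homozygous reference
    p_minor = base * (1 - config.error) + (1 - base) * config.error
    totals = rng.poisson(config.depth, size=config.n_sites)
    minor = rng.binomial(totals, p_minor)
    return [
        AlleleDepths(site, p=int(mi), q=int(t - mi))
        for site, t, mi in zip(sites, totals, minor)
    ]
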