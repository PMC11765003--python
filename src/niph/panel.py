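"""SNV panel selection from a population cohort.

A useful NIPH panel targets sites that are highly heterozygous in the study
population, so that many families will have informative sites (mother
homozygous, father heterozygous).  Three filters run over a cohort genotype
matrix:

1. sites where the population is overwhelmingly homozygous-reference are set
   aside as *common* (uninformative);
2. sites whose observed heterozygote frequency exceeds the upper window bound
   are excluded as genotyping artefacts (a heterozygote excess that strong is
   not Mendelian);
3. the remaining sites must not deviate from Hardy-Weinberg equilibrium
   (HWE), which flags residual genotyping error.

A separate minor-allele-frequency filter (``maf_filter``) is applied upstream
when candidate sites come from population databases rather than from the
cohort itself.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CohortGenotypes, SNVSite

logger = logging.getLogger(__name__)


class PanelStatus(enum.Enum):
    COMMON = "common"
    SELECTED = "selected"
    EXCLUDED_HIGH_HET = "excluded_high_het"
    EXCLUDED_HWE = "excluded_hwe"
    EXCLUDED_LOW_HET = "excluded_low_het"
    EXCLUDED_MAF = "excluded_maf"


@dataclass(frozen=True)
class PanelVariant:
    site: SNVSite
    het_degree: float  # percent of non-missing individuals heterozygous
    hwe_p: float
    maf: float
    status: PanelStatus

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_degree <= 100.0:
            raise ValueError("het_degree outside [0, 100]")
        if not 0.0 <= self.hwe_p <= 1.0:
            raise ValueError("hwe_p outside [0, 1]")


def heterozygosity_degree(calls_at_site) -> float:
    """Percent of non-missing individuals heterozygous at one site.

    ``calls_at_site`` is an integer vector of genotype codes
    (0=hom_ref, 1=het, 2=hom_alt, -1=missing).
    """
    calls = np.asarray(calls_at_site)
    non_missing = int((calls >= 0).sum())
    if non_missing == 0:
        raise ValueError("all genotypes missing at site")
    return 100.0 * int((calls == 1).sum()) / non_missing


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "chi2") -> float:
    """P-value for departure from Hardy-Weinberg genotype proportions.

    ``method='chi2'``: chi-square goodness of fit with 1 df, no continuity
    correction, against expectations from the sample allele frequency.
    ``method='exact'``: conditional exact test enumerating heterozygote
    counts given the observed allele counts.

    A monomorphic site (one allele absent) cannot deviate and returns 1.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    if n_ref == 0 or n_alt == 0:
        logger.debug("monomorphic site: HWE p set to 1")
        return 1.0
    if method == "chi2":
        p = n_ref / (2 * n)
        expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
        statistic = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(statistic, df=1))
    if method == "exact":
        return _hwe_exact(n_hom_ref, n_het, n_hom_alt)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Conditional exact HWE test (sum of probabilities <= observed).

    Enumerates all heterozygote counts compatible with the observed minor
    allele count; probabilities follow the hypergeometric-type distribution
    of heterozygote counts under HWE conditional on allele counts.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # log-probability up to a constant: P(het = h | n, n_minor)
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = []
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            logps.append(-math.inf)
            continue
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_major + 1)
        )
        logps.append(lp)
    m = max(logps)
    ps = np.exp(np.array(logps) - m)
    ps /= ps.sum()
    p_obs = ps[list(hets).index(n_het)]
    return float(ps[ps <= p_obs * (1 + 1e-12)].sum())


def maf_filter(site_freqs: dict, maf_min: float = 0.01) -> list:
    """Retain sites whose minor allele frequency exceeds ``maf_min``.

    ``site_freqs`` maps a site (any hashable) to its alt-allele frequency in
    the reference population.  Returns the retained keys in input order.
    """
    retained = []
    for site, freq in site_freqs.items():
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"allele frequency {freq} outside [0, 1] at {site}")
        if min(freq, 1.0 - freq) > maf_min:
            retained.append(site)
    logger.info("MAF filter: %d of %d sites retained (MAF > %g)",
                len(retained), len(site_freqs), maf_min)
    return retained


def select_panel(
    cohort: CohortGenotypes,
    het_min: float = 10.0,
    het_max: float = 90.0,
    hwe_alpha: float = 0.05,
    common_hom_ref_frac: float = 0.95,
    hwe_method: str = "chi2",
) -> list[PanelVariant]:
    """Classify every cohort site and mark the selected panel.

    Decision order per site (each site gets exactly one status):

    * ``common`` when the hom-ref fraction is strictly above
      ``common_hom_ref_frac`` (too monomorphic to be informative);
    * ``excluded_high_het`` when the heterozygote degree is strictly above
      ``het_max`` percent (non-Mendelian genotyping artefact);
    * ``excluded_low_het`` when below ``het_min`` (and not common);
    * within the inclusive window, ``selected`` when the HWE p-value is
      strictly above ``hwe_alpha``, else ``excluded_hwe``.

    Missing genotypes are excluded from every denominator.
    """
    if cohort.n_sites == 0:
        raise ValueError("empty cohort")
    out: list[PanelVariant] = []
    for i, site in enumerate(cohort.sites):
        calls = cohort.calls[i]
        n0 = int((calls == 0).sum())
        n1 = int((calls == 1).sum())
        n2 = int((calls == 2).sum())
        nn = n0 + n1 + n2
        if nn == 0:
            raise ValueError(f"all genotypes missing at {site.key}")
        het = 100.0 * n1 / nn
        p_alt = (2 * n2 + n1) / (2 * nn)
        maf = min(p_alt, 1.0 - p_alt)
        hwe_p = hwe_test(n0, n1, n2, method=hwe_method)
        if n0 / nn > common_hom_ref_frac:
            status = PanelStatus.COMMON
        elif het > het_max:
            status = PanelStatus.EXCLUDED_HIGH_HET
        elif het < het_min:
            status = PanelStatus.EXCLUDED_LOW_HET
        elif hwe_p > hwe_alpha:
            status = PanelStatus.SELECTED
        else:
            status = PanelStatus.EXCLUDED_HWE
        out.append(PanelVariant(site, het, hwe_p, maf, status))
    counts = status_counts(out)
    logger.info(
        "panel selection over %d sites: %s",
        cohort.n_sites,
        ", ".join(f"{k.value}={v}" for k, v in counts.items() if v),
    )
    return out


def status_counts(variants: list[PanelVariant]) -> dict[PanelStatus, int]:
    counts = {s: 0 for s in PanelStatus}
    for v in variants:
        counts[v.status] += 1
    return counts
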