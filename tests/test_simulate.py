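"""Synthetic-data generators: determinism and parameter recovery."""

import math

import numpy as np
import pytest

from niph.calling import fetal_fraction
from niph.classify import SNVGroup, classify_family, pq_allele_map
from niph.core import Genotype as GT, orient_depths
from niph.panel import PanelStatus, select_panel, status_counts
from niph.simulate import (
    SimConfig,
    SpikeConfig,
    simulate_cohort,
    simulate_family,
    simulate_spike,
    simulate_structured_cohort,
)


def informative_ffs(fam, truth=None, carried_only=False):
    """Observed ff at group-i SNVs (optionally only truth-present sites)."""
    cls = classify_family(fam)
    pq = pq_allele_map(cls, fam.mother)
    rep = fam.cfdna_replicates[0][1]
    out = []
    for c in cls:
        if c.group is not SNVGroup.I_INFORMATIVE:
            continue
        if carried_only:
            carries = fam.cvs[c.site.key].carries(c.fetal_specific_allele, c.site)
            if not carries:
                continue
        d = orient_depths(rep[c.site.key], pq[c.site.key])
        out.append(fetal_fraction(d.p, d.q))
    return out


def group_ii_error_rates(fam):
    cls = classify_family(fam)
    pq = pq_allele_map(cls, fam.mother)
    rep = fam.cfdna_replicates[0][1]
    return [
        fetal_fraction(*(lambda d: (d.p, d.q))(orient_depths(rep[c.site.key], pq[c.site.key])))
        for c in cls
        if c.group is SNVGroup.II_CUTOFF
    ]


class TestCohort:
    def test_deterministic_under_seed(self):
        a = simulate_cohort(SimConfig(n_sites=30, seed=9))
        b = simulate_cohort(SimConfig(n_sites=30, seed=9))
        assert np.array_equal(a.calls, b.calls)
        assert a.sites == b.sites

    def test_het_count_near_binomial_expectation(self):
        cohort = simulate_cohort(SimConfig(n_sites=200, allele_freqs=0.5, seed=2))
        het_per_site = (cohort.calls == 1).mean(axis=1) * 100
        sd = 100 * math.sqrt(0.5 * 0.5 / 96)
        # averaged over 200 sites the SE shrinks by sqrt(200)
        assert abs(het_per_site.mean() - 50.0) < 3 * sd / math.sqrt(200)

    def test_rare_allele_site_classified_common(self):
        cohort = simulate_cohort(SimConfig(n_sites=50, allele_freqs=0.001, seed=3))
        variants = select_panel(cohort)
        frac_common = status_counts(variants)[PanelStatus.COMMON] / 50
        assert frac_common > 0.9

    def test_structured_cohort_reproduces_requested_class_counts(self):
        cohort = simulate_structured_cohort(seed=123)
        counts = status_counts(select_panel(cohort))
        assert counts[PanelStatus.COMMON] == 324
        assert counts[PanelStatus.EXCLUDED_HIGH_HET] == 65
        assert counts[PanelStatus.EXCLUDED_HWE] == 52
        assert counts[PanelStatus.SELECTED] == 219


class TestFamily:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_sites=40, seed=17)
        fam_a, _ = simulate_family(cfg)
        fam_b, _ = simulate_family(cfg)
        assert fam_a.mother == fam_b.mother
        da = fam_a.cfdna_replicates[0][1]
        db = fam_b.cfdna_replicates[0][1]
        assert {k: (d.ref_count, d.alt_count) for k, d in da.items()} == {
            k: (d.ref_count, d.alt_count) for k, d in db.items()
        }

    def test_zero_fetal_fraction_zero_error_gives_zero_ff(self):
        cfg = SimConfig(n_sites=60, fetal_fraction=0.0, error=0.0, seed=4)
        fam, _ = simulate_family(cfg, include_pathogenic=False)
        assert all(ff == 0.0 for ff in informative_ffs(fam))

    @pytest.mark.parametrize("f", [0.03, 0.10])
    def test_mean_ff_recovers_fetal_fraction(self, f):
        cfg = SimConfig(n_sites=400, fetal_fraction=f, error=0.0, seed=6)
        fam, _ = simulate_family(cfg, transmitted_paternal="path", include_pathogenic=False)
        ffs = informative_ffs(fam, carried_only=True)
        assert len(ffs) >= 30
        se = np.std(ffs, ddof=1) / math.sqrt(len(ffs))
        assert abs(np.mean(ffs) - 100 * f) < 3 * se

    def test_mean_error_rate_recovers_two_epsilon(self):
        eps = 0.003
        cfg = SimConfig(n_sites=400, fetal_fraction=0.1, error=eps, seed=8)
        fam, _ = simulate_family(cfg, include_pathogenic=False)
        rates = group_ii_error_rates(fam)
        assert len(rates) >= 30
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(np.mean(rates) - 200 * eps) < 3 * se

    def test_cvs_equals_fetal_genotypes_and_is_mendelian(self):
        fam, truth = simulate_family(SimConfig(n_sites=50, seed=10))
        assert fam.cvs == truth.fetal_genotypes  # construction contract

    def test_supplied_parent_genotypes_respected(self):
        cfg = SimConfig(n_sites=4, seed=1)
        sites = simulate_family(cfg, include_pathogenic=False)[0].panel
        mother = {s.key: GT.HOM_REF for s in sites}
        father = {s.key: GT.HET for s in sites}
        fam, _ = simulate_family(
            cfg, include_pathogenic=False, mother_counts=mother, father_counts=father
        )
        assert fam.mother == mother
        assert fam.father == father


class TestSpike:
    def test_deterministic_under_seed(self):
        a = simulate_spike(SpikeConfig(seed=5))
        b = simulate_spike(SpikeConfig(seed=5))
        assert [(d.p, d.q) for d in a] == [(d.p, d.q) for d in b]

    def test_mean_minor_fraction_recovers_spike_fraction(self):
        depths = simulate_spike(SpikeConfig(spike_fraction=0.10, error=0.0, seed=12))
        fracs = [fetal_fraction(d.p, d.q) for d in depths]
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 10.0) < 3 * se

    def test_zero_spike_measures_error_rate_only(self):
        eps = 0.003
        depths = simulate_spike(SpikeConfig(spike_fraction=0.0, error=eps, seed=13))
        fracs = [fetal_fraction(d.p, d.q) for d in depths]
        se = np.std(fracs, ddof=1) / math.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 200 * eps) < 3 * se

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SpikeConfig(spike_fraction=1.5)
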