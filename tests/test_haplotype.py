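"""Paternal phasing, majority-vote inheritance, and diagnostic mapping."""

import pytest

from niph.calling import AlleleCall, Call, CallLabel, Truth
from niph.core import (
    CarrierState,
    FamilyRecord,
    Genotype as GT,
    PathogenicAnnotation,
    SNVSite,
)
from niph.haplotype import (
    Inherited,
    PaternalHaplotypes,
    PhaseSource,
    Verdict,
    combine_replicates,
    diagnose,
    infer_inheritance,
    phase_father_from_cvs,
    phase_father_from_grandparents,
    phase_from_grandparents,
)
from niph.simulate import SimConfig, simulate_family
from niph.pipeline import analyze_family
from conftest import make_site

HGVS = "NM_000518.5:c.[93-21G>A]"
PATH_SITE = SNVSite("11", 5000, "G", "A", HGVS)


def family_with_cvs(cvs_snv, cvs_path, father_path=GT.HET, mother_path=GT.HOM_REF):
    snv = make_site(pos=100)
    return FamilyRecord(
        family_id="T",
        panel=[snv, PATH_SITE],
        mother={snv.key: GT.HOM_REF, PATH_SITE.key: mother_path},
        father={snv.key: GT.HET, PATH_SITE.key: father_path},
        cvs={snv.key: cvs_snv, PATH_SITE.key: cvs_path},
        father_pathogenic=[PathogenicAnnotation(HGVS, CarrierState.HET)],
        cfdna_replicates=[("r1", {})],
    ), snv


class TestPhaseFromCvs:
    def test_transmitted_allele_is_cvs_allele_not_from_mother(self):
        fam, snv = family_with_cvs(GT.HET, GT.HOM_REF)
        haps = phase_father_from_cvs(fam)
        # fetus het at the SNV, pathogenic variant not transmitted:
        # the transmitted (wild-type) haplotype carries the alt allele
        assert haps.hap_wt[snv.key] == snv.alt_allele
        assert haps.hap_path[snv.key] == snv.ref_allele
        assert haps.phase_source is PhaseSource.CVS

    def test_transmitted_allele_complement(self):
        fam, snv = family_with_cvs(GT.HOM_REF, GT.HOM_REF)
        haps = phase_father_from_cvs(fam)
        assert haps.hap_wt[snv.key] == snv.ref_allele

    def test_anchor_from_homozygous_affected_cvs(self):
        # parents share the variant (both het); CVS homozygous-affected
        fam, snv = family_with_cvs(GT.HET, GT.HOM_ALT, mother_path=GT.HET)
        haps = phase_father_from_cvs(fam)
        # the transmitted paternal haplotype is the pathogenic one
        assert haps.hap_path[snv.key] == snv.alt_allele
        assert haps.anchor == "hap_path"

    def test_shared_variant_het_cvs_cannot_anchor(self):
        fam, _ = family_with_cvs(GT.HET, GT.HET, mother_path=GT.HET)
        with pytest.raises(ValueError, match="anchor"):
            phase_father_from_cvs(fam)

    def test_missing_cvs_directs_to_other_sources(self):
        fam, _ = family_with_cvs(GT.HET, GT.HOM_REF)
        fam.cvs = None
        with pytest.raises(ValueError, match="grandparental|external"):
            phase_father_from_cvs(fam)


class TestPhaseFromGrandparents:
    def test_forced_transmission(self, site):
        parent = {site.key: GT.HET}
        haps = phase_from_grandparents(
            parent,
            grandfather={site.key: GT.HOM_REF},
            grandmother={site.key: GT.HOM_ALT},
            panel=[site],
            pathogenic_site_keys=set(),
        )
        assert haps.hap_wt[site.key] == site.ref_allele  # from grandfather
        assert haps.hap_path[site.key] == site.alt_allele

    def test_double_het_grandparents_leave_site_unphased(self, site):
        haps = phase_from_grandparents(
            {site.key: GT.HET},
            grandfather={site.key: GT.HET},
            grandmother={site.key: GT.HET},
            panel=[site],
            pathogenic_site_keys=set(),
        )
        assert site.key in haps.unphased_sites
        assert site.key not in haps.hap_wt

    def test_mendelian_inconsistency_names_site(self, site):
        with pytest.raises(ValueError, match=site.key):
            phase_from_grandparents(
                {site.key: GT.HET},
                grandfather={site.key: GT.HOM_REF},
                grandmother={site.key: GT.HOM_REF},
                panel=[site],
                pathogenic_site_keys=set(),
            )

    def test_pathogenic_origin_anchors_haplotypes(self, site):
        # father het at SNV and at the pathogenic variant; the variant comes
        # from the paternal grandfather, so hap_path is the grandfather's
        parent = {site.key: GT.HET, PATH_SITE.key: GT.HET}
        haps = phase_from_grandparents(
            parent,
            grandfather={site.key: GT.HOM_ALT, PATH_SITE.key: GT.HET},
            grandmother={site.key: GT.HOM_REF, PATH_SITE.key: GT.HOM_REF},
            panel=[site, PATH_SITE],
            pathogenic_site_keys={PATH_SITE.key},
        )
        assert haps.anchor == "hap_path"
        assert haps.hap_path[PATH_SITE.key] == PATH_SITE.alt_allele
        assert haps.hap_path[site.key] == site.alt_allele

    def test_agrees_with_cvs_phasing_on_simulated_family(self):
        cfg = SimConfig(n_sites=80, fetal_fraction=0.1, seed=11)
        fam, truth = simulate_family(cfg, transmitted_paternal="path")
        by_cvs = phase_father_from_cvs(fam)
        by_gp = phase_father_from_grandparents(fam)
        for key in set(by_cvs.hap_path) & set(by_gp.hap_path):
            assert by_cvs.hap_path[key] == by_gp.hap_path[key]
            assert by_cvs.hap_wt[key] == by_gp.hap_wt[key]


def vote_calls(haps, sites, pattern):
    """Build calls from (site, positive?) pairs; fetal-specific = alt."""
    calls = []
    for site, positive in zip(sites, pattern):
        calls.append(
            AlleleCall(
                site=site, replicate_id="r", fetal_specific_allele=site.alt_allele,
                p=0, q=1, ff=10.0 if positive else 0.0, cutoff=1.0,
                call=Call.POSITIVE if positive else Call.NEGATIVE,
            )
        )
    return calls


def haps_with_alt_on(path_sites, wt_sites):
    hap_wt, hap_path = {}, {}
    for s in path_sites:
        hap_path[s.key] = s.alt_allele
        hap_wt[s.key] = s.ref_allele
    for s in wt_sites:
        hap_wt[s.key] = s.alt_allele
        hap_path[s.key] = s.ref_allele
    return PaternalHaplotypes(
        hap_wt=hap_wt, hap_path=hap_path, anchor="hap_path",
        phase_source=PhaseSource.EXTERNAL,
    )


class TestInferInheritance:
    def test_majority_seven_of_eleven(self):
        sites = [make_site(pos=100 + i) for i in range(11)]
        haps = haps_with_alt_on(sites, [])
        calls = vote_calls(haps, sites, [True] * 7 + [False] * 4)
        r = infer_inheritance(calls, haps, "1", "275_a")
        assert r.inherited is Inherited.HAP_PATH
        assert (r.n_support, r.n_informative) == (7, 11)
        assert r.concordance_rounded == 64.0

    def test_no_informative_sites_not_applicable(self):
        haps = haps_with_alt_on([], [])
        r = infer_inheritance([], haps, "14")
        assert r.inherited is Inherited.NOT_APPLICABLE
        assert r.concordance is None

    def test_exact_tie_inconclusive(self):
        sites = [make_site(pos=100 + i) for i in range(10)]
        haps = haps_with_alt_on(sites, [])
        calls = vote_calls(haps, sites, [True] * 5 + [False] * 5)
        assert infer_inheritance(calls, haps).inherited is Inherited.INCONCLUSIVE

    def test_true_negatives_support_the_other_haplotype(self):
        # all calls negative, fetal-specific alleles all on hap_path:
        # the wild-type haplotype must win (families resolved purely by TNs)
        sites = [make_site(pos=100 + i) for i in range(22)]
        haps = haps_with_alt_on(sites, [])
        calls = vote_calls(haps, sites, [False] * 22)
        r = infer_inheritance(calls, haps)
        assert r.inherited is Inherited.HAP_WT
        assert r.concordance == 100.0

    def test_votes_partition_informative_calls(self):
        sites = [make_site(pos=100 + i) for i in range(9)]
        haps = haps_with_alt_on(sites[:5], sites[5:])
        calls = vote_calls(haps, sites, [True, False] * 4 + [True])
        r = infer_inheritance(calls, haps)
        assert r.n_informative == 9
        assert r.n_support >= (9 + 1) // 2

    def test_unphased_sites_excluded_from_voting(self):
        sites = [make_site(pos=100 + i) for i in range(4)]
        haps = haps_with_alt_on(sites[:2], [])
        calls = vote_calls(haps, sites, [True] * 4)  # two sites unphased
        assert infer_inheritance(calls, haps).n_informative == 2

    def test_perfect_simulated_family_is_fully_concordant(self):
        cfg = SimConfig(n_sites=60, fetal_fraction=0.10, error=0.0, seed=5)
        fam, truth = simulate_family(cfg, transmitted_paternal="path")
        analysis = analyze_family(fam)
        r = analysis.replicates[0].inheritance
        assert r.inherited is Inherited.HAP_PATH
        assert r.concordance == 100.0


class TestCombineAndDiagnose:
    def _res(self, inherited, n=10, k=8):
        from niph.haplotype import InheritanceResult

        return InheritanceResult("f", "r", inherited, k, n)

    def test_agreeing_replicates(self):
        rs = [self._res(Inherited.HAP_WT), self._res(Inherited.HAP_WT)]
        assert combine_replicates(rs) is Inherited.HAP_WT

    def test_disagreeing_replicates_inconclusive(self):
        rs = [self._res(Inherited.HAP_WT), self._res(Inherited.HAP_PATH)]
        assert combine_replicates(rs) is Inherited.INCONCLUSIVE

    def test_all_empty_not_applicable(self):
        rs = [self._res(Inherited.NOT_APPLICABLE, n=0, k=0)]
        assert combine_replicates(rs) is Inherited.NOT_APPLICABLE

    @pytest.mark.parametrize(
        "inherited, verdict",
        [
            (Inherited.HAP_WT, Verdict.INVASIVE_AVOIDED),
            (Inherited.HAP_PATH, Verdict.INVASIVE_RECOMMENDED),
            (Inherited.INCONCLUSIVE, Verdict.NOT_APPLICABLE),
            (Inherited.NOT_APPLICABLE, Verdict.NOT_APPLICABLE),
        ],
    )
    def test_verdict_mapping(self, inherited, verdict):
        assert diagnose(inherited, "f").verdict is verdict

    def test_non_carrier_father_always_avoids_invasive(self):
        d = diagnose(Inherited.HAP_PATH, "f", anchor="wt_wt")
        assert d.verdict is Verdict.INVASIVE_AVOIDED
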