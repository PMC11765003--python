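"""Readers and writers for the standard formats the pipeline touches.

VCF (v4.2, GT and AD fields) for cohort and family genotypes, BED for panel
intervals, TSV for genotype/depth/phase tables, and TSV + JSON for family
reports.  Coordinates are 1-based inclusive in VCF/TSV and half-open
0-based in BED; conversion happens only here.  Only biallelic SNVs are
supported — indels and multiallelic records are skipped with a logged
count.  The genotype TSV dialect is tab-separated, header row, UTF-8, '.'
for missing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    AlleleDepths,
    CODE_GT,
    CohortGenotypes,
    GT_CODE,
    Genotype,
    GenotypeMap,
    SiteDepths,
    SNVSite,
    orient_depths,
)
from .haplotype import PaternalHaplotypes, PhaseSource

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}
_STR_GT = {
    "0/0": Genotype.HOM_REF, "0|0": Genotype.HOM_REF,
    "0/1": Genotype.HET, "1/0": Genotype.HET, "0|1": Genotype.HET, "1|0": Genotype.HET,
    "1/1": Genotype.HOM_ALT, "1|1": Genotype.HOM_ALT,
    "./.": Genotype.MISSING, ".": Genotype.MISSING, ".|.": Genotype.MISSING,
}


def _is_biallelic_snv(ref: str, alts: tuple) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref != alts[0]
        and ref in "ACGT"
        and alts[0] in "ACGT"
    )


def read_genotype_vcf(path: PathLike) -> CohortGenotypes:
    """Read a multi-sample VCF into a cohort genotype matrix.

    Non-SNV and multiallelic records are skipped (counted in the log).
    Genotypes map 0/0 -> hom_ref, 0/1 -> het, 1/1 -> hom_alt, ./. -> missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    sites: list[SNVSite] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if not _is_biallelic_snv(rec.REF, tuple(rec.ALT)):
            skipped += 1
            continue
        sites.append(
            SNVSite(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID or None)
        )
        # gts012: 0=hom_ref 1=het 2=hom_alt 3=unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = -1
        rows.append(gt)
    vcf.close()
    if skipped:
        logger.info("read_genotype_vcf: skipped %d non-SNV/multiallelic records", skipped)
    if not sites:
        raise ValueError(f"no biallelic SNV records in {path}")
    return CohortGenotypes(
        sites=sites, individuals=individuals, calls=np.vstack(rows)
    )


def write_genotype_vcf(cohort: CohortGenotypes, path: PathLike) -> None:
    """Write a cohort matrix as a minimal VCFv4.2 text file."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({s.chrom for s in cohort.sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.individuals)
            + "\n"
        )
        for i, s in enumerate(cohort.sites):
            gts = "\t".join(
                _GT_STR[CODE_GT[int(code)]] for code in cohort.calls[i]
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id or '.'}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotype_tsv(path: PathLike) -> CohortGenotypes:
    """Read the genotype TSV dialect: chrom, pos, ref, alt, id, then samples."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    fixed = ["chrom", "pos", "ref", "alt", "id"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing columns: {missing}")
    samples = [c for c in df.columns if c not in fixed]
    sites = [
        SNVSite(r.chrom, int(r.pos), r.ref, r.alt, r.id or None)
        for r in df.itertuples()
    ]
    calls = np.empty((len(sites), len(samples)), dtype=np.int8)
    for j, col in enumerate(samples):
        for i, val in enumerate(df[col]):
            try:
                calls[i, j] = GT_CODE[_STR_GT[val]]
            except KeyError:
                raise ValueError(f"unparseable genotype {val!r} in column {col}") from None
    return CohortGenotypes(sites=sites, individuals=samples, calls=calls)


def write_genotype_tsv(cohort: CohortGenotypes, path: PathLike) -> None:
    rows = []
    for i, s in enumerate(cohort.sites):
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
               "alt": s.alt_allele, "id": s.id or "."}
        for j, ind in enumerate(cohort.individuals):
            row[ind] = _GT_STR[CODE_GT[int(cohort.calls[i, j])]]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_depth_table(path: PathLike, panel: list[SNVSite]) -> dict[str, SiteDepths]:
    """Read per-site ref/alt read counts (TSV: chrom, pos, ref, alt,
    ref_count, alt_count) for the given panel."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"depth TSV missing columns: {missing}")
    by_key = {s.key: s for s in panel}
    out: dict[str, SiteDepths] = {}
    for r in df.itertuples():
        key = f"{r.chrom}:{int(r.pos)}:{r.ref}:{r.alt}"
        site = by_key.get(key)
        if site is None:
            continue
        if r.ref_count < 0 or r.alt_count < 0:
            raise ValueError(f"negative read count at {key}")
        out[key] = SiteDepths(site, int(r.ref_count), int(r.alt_count))
    return out


def write_depth_table(depths: dict[str, SiteDepths], path: PathLike) -> None:
    rows = [
        {
            "chrom": d.site.chrom, "pos": d.site.pos,
            "ref": d.site.ref_allele, "alt": d.site.alt_allele,
            "ref_count": d.ref_count, "alt_count": d.alt_count,
        }
        for d in sorted(depths.values(), key=lambda d: d.site)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_depths(
    path: PathLike,
    panel: list[SNVSite],
    fetal_specific_map: dict[str, str],
) -> dict[str, AlleleDepths]:
    """Read a depth table and orient p/q per the fetal-specific allele map.

    ``fetal_specific_map`` names, per site key, the allele whose reads count
    as ``p``.  Sites in the map but absent from the file raise an error
    listing them; file sites absent from the map are dropped (their p role
    is undefined).
    """
    raw = read_depth_table(path, panel)
    absent = sorted(set(fetal_specific_map) - set(raw))
    if absent:
        raise ValueError(f"sites named in fetal_specific_map missing from {path}: {absent}")
    return {
        key: orient_depths(raw[key], allele)
        for key, allele in fetal_specific_map.items()
    }


def write_panel_bed(sites: list[SNVSite], path: PathLike) -> None:
    """Panel intervals as BED (half-open, 0-based)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sorted(sites):
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.id or s.key}\n")


def write_panel_tsv(variants, path: PathLike) -> None:
    """Panel-selection results: site, het_degree, hwe_p, maf, status."""
    rows = [
        {
            "chrom": v.site.chrom, "pos": v.site.pos,
            "ref": v.site.ref_allele, "alt": v.site.alt_allele,
            "id": v.site.id or ".",
            "het_degree": f"{v.het_degree:.6g}",
            "hwe_p": f"{v.hwe_p:.6g}",
            "maf": f"{v.maf:.6g}",
            "status": v.status.value,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phase_tsv(
    path: PathLike,
    father: Optional[GenotypeMap] = None,
    panel: Optional[list[SNVSite]] = None,
) -> PaternalHaplotypes:
    """Load an external paternal phase (site, hap_wt allele, hap_path allele).

    When the father's genotypes are supplied, the phase is checked for
    consistency: at each phased site his genotype must contain exactly the
    two listed alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "pos", "ref", "alt", "hap_wt", "hap_path"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"phase TSV missing columns: {missing}")
    hap_wt: dict[str, str] = {}
    hap_path: dict[str, str] = {}
    by_key = {s.key: s for s in panel} if panel is not None else None
    for r in df.itertuples():
        key = f"{r.chrom}:{int(r.pos)}:{r.ref}:{r.alt}"
        if r.hap_wt == r.hap_path:
            raise ValueError(f"identical haplotype alleles at {key}")
        if {r.hap_wt, r.hap_path} != {r.ref, r.alt}:
            raise ValueError(f"phase alleles at {key} are not the site's ref/alt")
        if father is not None:
            site = by_key[key] if by_key else SNVSite(r.chrom, int(r.pos), r.ref, r.alt)
            gt = father.get(key, Genotype.MISSING)
            if gt is not Genotype.MISSING and gt is not Genotype.HET:
                raise ValueError(
                    f"phase file lists two alleles at {key} but father is {gt.value}"
                )
        hap_wt[key] = r.hap_wt
        hap_path[key] = r.hap_path
    return PaternalHaplotypes(
        hap_wt=hap_wt, hap_path=hap_path, anchor="hap_path",
        phase_source=PhaseSource.EXTERNAL,
    )


def write_phase_tsv(haps: PaternalHaplotypes, path: PathLike) -> None:
    rows = []
    for key in sorted(set(haps.hap_wt) & set(haps.hap_path)):
        chrom, pos, ref, alt = key.split(":")
        rows.append(
            {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
             "hap_wt": haps.hap_wt[key], "hap_path": haps.hap_path[key]}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_family_report(analysis, prefix: PathLike) -> tuple[Path, Path]:
    """Write a family analysis as <prefix>.calls.tsv and <prefix>.json.

    The TSV has one row per panel SNV per replicate (group, p, q, ff,
    cut-off, call, truth, label); the JSON carries cut-offs, per-replicate
    inheritance, and the diagnostic verdict.  Output is bit-stable for
    identical inputs.
    """
    from .classify import SNVGroup

    prefix = Path(prefix)
    if not analysis.family.cfdna_replicates:
        raise ValueError("family has no cfDNA replicates; nothing to report")
    calls_by = {
        (r.replicate_id, c.site.key): c
        for r in analysis.replicates
        for c in r.calls
    }
    rows = []
    for rep in analysis.replicates:
        for cls in analysis.classifications:
            c = calls_by.get((rep.replicate_id, cls.site.key))
            rows.append(
                {
                    "family": analysis.family.family_id,
                    "replicate": rep.replicate_id,
                    "chrom": cls.site.chrom,
                    "pos": cls.site.pos,
                    "ref": cls.site.ref_allele,
                    "alt": cls.site.alt_allele,
                    "id": cls.site.id or ".",
                    "group": cls.group.value,
                    "fetal_specific_allele": cls.fetal_specific_allele or ".",
                    "p": c.p if c else ".",
                    "q": c.q if c else ".",
                    "ff_percent": f"{c.ff:.6g}" if c else ".",
                    "cutoff_percent": f"{rep.cutoff.cutoff:.6g}",
                    "call": c.call.value if c else ".",
                    "truth": c.truth.value if c else ".",
                    "label": c.label.value if c else ".",
                }
            )
    calls_path = prefix.with_suffix(".calls.tsv")
    pd.DataFrame(rows).to_csv(calls_path, sep="\t", index=False)

    status = (
        "not_applicable" if analysis.n_informative == 0 else "analyzed"
    )
    doc = {
        "family": analysis.family.family_id,
        "status": status,
        "n_informative": analysis.n_informative,
        "group_counts": {g.value: n for g, n in analysis.group_counts.items()},
        "phase_source": (
            analysis.haplotypes.phase_source.value if analysis.haplotypes else None
        ),
        "replicates": [
            {
                "replicate": r.replicate_id,
                "max_error": r.cutoff.max_error,
                "sd_error": r.cutoff.sd_error,
                "cutoff": r.cutoff.cutoff,
                "inherited": r.inheritance.inherited.value,
                "n_support": r.inheritance.n_support,
                "n_informative": r.inheritance.n_informative,
                "concordance": r.inheritance.concordance,
            }
            for r in analysis.replicates
        ],
        "family_inherited": analysis.family_inherited.value,
        "verdict": analysis.diagnostic.verdict.value if analysis.diagnostic else None,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return calls_path, json_path
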