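"""Packaged reference tables from the β-thalassaemia NIPH validation study.

The assay this pipeline implements was validated on 17 Greek-Cypriot
families at risk for β-thalassaemia (21 cfDNA replicates; families 1–4 were
run in duplicate).  The raw sequencing data are not public, but the study's
summary tables are, and they serve two purposes here:

* as *inputs* for report-level analyses that need no simulation — published
  per-replicate error-rate cut-offs, per-replicate confusion counts with the
  transmitted paternal haplotype, spike-mixture summaries, per-family
  informative-SNV counts, and the family pedigree/HGVS genotype structure;
* as *expected values* the package's own arithmetic must reproduce
  (pooled sensitivity/specificity, cut-off and band arithmetic, family
  verdicts).

All loaders return pandas DataFrames read from the TSVs shipped under
``niph/data``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calling import AlleleCall, Call, CallLabel, Truth
from .core import SNVSite
from .haplotype import PaternalHaplotypes, PhaseSource


def _load(name: str) -> pd.DataFrame:
    with resources.files("niph.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def replicate_cutoffs() -> pd.DataFrame:
    """Published per-replicate error-rate summaries: family, replicate,
    max_error, sd_error, cutoff (all percent, three decimals as printed)."""
    return _load("replicate_cutoffs.tsv")


def call_outcomes() -> pd.DataFrame:
    """Published per-replicate confusion counts (tp, fn, tn, fp) and the
    paternal haplotype the fetus actually inherited ('wt'/'path'; 'none'
    for the family with no informative SNVs)."""
    return _load("call_outcomes.tsv")


def spike_summaries() -> pd.DataFrame:
    """Published spike-mixture statistics per spiked fraction: n_sites,
    mean, sd, median, and the mean ± 1 SD band (percent)."""
    return _load("spike_summaries.tsv")


def informative_counts() -> pd.DataFrame:
    """Published number of informative SNVs per family."""
    return _load("informative_counts.tsv")


def family_genotypes() -> pd.DataFrame:
    """Published family structures: member roles, sample ids, and HGVS
    genotypes at the HBB pathogenic variants."""
    return _load("family_genotypes.tsv")


def pooled_confusion_counts() -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) summed over all published replicates."""
    df = call_outcomes()
    return (
        int(df.tp.sum()),
        int(df.fn.sum()),
        int(df.tn.sum()),
        int(df.fp.sum()),
    )


def reconstruct_replicate_calls(
    row,
) -> tuple[list[AlleleCall], PaternalHaplotypes]:
    """Rebuild per-site allele calls for one published replicate.

    The published tables give, per replicate, how many informative sites
    were truth-present vs truth-absent and how each was called, plus which
    paternal haplotype was transmitted.  That fixes everything the
    inheritance vote consumes: truth-present sites carry their
    fetal-specific allele on the transmitted haplotype, truth-absent sites
    on the untransmitted one.  Site coordinates are synthetic placeholders;
    the vote depends only on call/haplotype structure.
    """
    transmitted = row.transmitted  # 'wt', 'path', or 'none'
    hap_wt: dict[str, str] = {}
    hap_path: dict[str, str] = {}
    calls: list[AlleleCall] = []
    pos = 5_000_000
    cutoff = 1.0

    def add_site(on_transmitted: bool, call: Call, label: CallLabel, truth: Truth):
        nonlocal pos
        pos += 101
        site = SNVSite("11", pos, "A", "G")
        fs = site.alt_allele
        target = transmitted if on_transmitted else ("wt" if transmitted == "path" else "path")
        if target == "wt":
            hap_wt[site.key] = fs
            hap_path[site.key] = site.ref_allele
        else:
            hap_path[site.key] = fs
            hap_wt[site.key] = site.ref_allele
        ff = 10.0 if call is Call.POSITIVE else 0.0
        calls.append(
            AlleleCall(
                site=site, replicate_id=str(row.replicate),
                fetal_specific_allele=fs, p=0, q=1, ff=ff, cutoff=cutoff,
                call=call, truth=truth, label=label,
            )
        )

    if transmitted != "none":
        for _ in range(int(row.tp)):
            add_site(True, Call.POSITIVE, CallLabel.TP, Truth.PRESENT)
        for _ in range(int(row.fn)):
            add_site(True, Call.NEGATIVE, CallLabel.FN, Truth.PRESENT)
        for _ in range(int(row.tn)):
            add_site(False, Call.NEGATIVE, CallLabel.TN, Truth.ABSENT)
        for _ in range(int(row.fp)):
            add_site(False, Call.POSITIVE, CallLabel.FP, Truth.ABSENT)

    haps = PaternalHaplotypes(
        hap_wt=hap_wt, hap_path=hap_path, anchor="hap_path",
        phase_source=PhaseSource.EXTERNAL,
    )
    return calls, haps
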