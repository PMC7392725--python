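"""Allelic imbalance in methylation (AIM) and parent-of-origin resolution.

At a heterozygous SNP, unequal representation of the two alleles among
methylation-enriched reads indicates allele-biased methylation. AIM is the
Diff/Sum of allele counts, ``(Ref - Alt) / (Ref + Alt)``, per sample;
where parental phase is known it is re-expressed as ``(Pat - Mat) / (Pat +
Mat)``. Loci informative for parent of origin are those where the two
parents are homozygous for different alleles, so the child is an obligate
heterozygote.

With a symmetric threshold (default 0.5: values in [-0.5, 0.5] count as
heterozygous/biallelic) each phased locus falls in exactly one of five
categories comparing control and knockdown: biallelic_stable,
monoallelic_stable, loss_of_monoallelic, gain_of_monoallelic, allelic_flip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORY_NAMES = (
    "biallelic_stable",
    "monoallelic_stable",
    "loss_of_monoallelic",
    "gain_of_monoallelic",
    "allelic_flip",
)


def pileup_allele_counts(
    annotations: pd.DataFrame,
    sites: pd.DataFrame,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Per-site, per-sample ref/alt read counts from SNP base annotations.

    ``annotations`` carries one row per (read, overlapped site): ``sample``,
    ``chrom``, ``pos``, ``base``. Bases matching neither allele are tallied
    in ``n_other`` and excluded from the counts. Sites with ``n_ref + n_alt
    < min_coverage`` in a sample are dropped for that sample.
    """
    required = {"sample", "chrom", "pos", "base"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations must have columns {sorted(required)}")
    merged = annotations.merge(sites[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos"], how="inner")
    if len(merged) < len(annotations):
        raise ValueError("annotation at a site absent from the site list")
    merged["is_ref"] = merged["base"] == merged["ref"]
    merged["is_alt"] = merged["base"] == merged["alt"]
    grouped = merged.groupby(["sample", "chrom", "pos"], sort=True).agg(
        n_ref=("is_ref", "sum"), n_alt=("is_alt", "sum"), n_total=("base", "size")
    )
    grouped["n_other"] = grouped["n_total"] - grouped["n_ref"] - grouped["n_alt"]
    out = grouped.reset_index().drop(columns="n_total")
    return out[out["n_ref"] + out["n_alt"] >= min_coverage].reset_index(drop=True)


def aim_values(
    counts_ct: pd.DataFrame,
    counts_kd: pd.DataFrame,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """AIM Diff/Sum per site for loci covered in both samples.

    ``aim = (n_ref - n_alt) / (n_ref + n_alt)`` per sample (sign convention:
    reference-biased loci are positive). When ``sites`` carries
    ``maternal_allele``/``paternal_allele``, parent-of-origin values ``poo =
    (pat - mat) / (pat + mat)`` are added by relabeling ref/alt.
    """
    merged = counts_ct.merge(
        counts_kd, on=["chrom", "pos"], suffixes=("_ct", "_kd"), validate="one_to_one"
    )
    for cond in ("ct", "kd"):
        ref, alt = merged[f"n_ref_{cond}"], merged[f"n_alt_{cond}"]
        merged[f"aim_{cond}"] = (ref - alt) / (ref + alt)
    cols = ["chrom", "pos", "n_ref_ct", "n_alt_ct", "n_ref_kd", "n_alt_kd", "aim_ct", "aim_kd"]
    out = merged[cols].copy()
    if sites is not None and {"maternal_allele", "paternal_allele"} <= set(sites.columns):
        phased = out.merge(
            sites[["chrom", "pos", "ref", "alt", "maternal_allele", "paternal_allele"]],
            on=["chrom", "pos"],
        )
        ref_is_pat = phased["paternal_allele"] == phased["ref"]
        sign = np.where(ref_is_pat, 1.0, -1.0)
        out = phased.assign(poo_ct=sign * phased["aim_ct"], poo_kd=sign * phased["aim_kd"])
    return out


def obligate_het_loci(parental: pd.DataFrame) -> pd.DataFrame:
    """Loci where the parents are homozygous for different alleles.

    ``parental`` needs ``chrom``, ``pos``, ``ref``, ``alt`` and genotype
    columns ``maternal_gt``/``paternal_gt`` ("A" or "A/A" style; het calls
    like "A/G" are dropped) or pre-resolved ``maternal_allele``/
    ``paternal_allele`` single-base columns. Loci whose parental alleles are
    not {ref, alt} are flagged inconsistent and dropped.
    """
    df = parental.copy()
    for parent in ("maternal", "paternal"):
        if f"{parent}_allele" not in df.columns:
            calls = df[f"{parent}_gt"].astype(str).str.replace("|", "/", regex=False)
            parts = calls.str.split("/")
            hom = parts.map(lambda p: len(set(p)) == 1)
            df = df[hom].copy()
            df[f"{parent}_allele"] = calls.str.split("/").str[0]
    discordant = df["maternal_allele"] != df["paternal_allele"]
    consistent = (
        df["maternal_allele"].eq(df["ref"]) | df["maternal_allele"].eq(df["alt"])
    ) & (df["paternal_allele"].eq(df["ref"]) | df["paternal_allele"].eq(df["alt"]))
    out = df[discordant & consistent].copy()
    out["mat_is_ref"] = out["maternal_allele"] == out["ref"]
    return out.reset_index(drop=True)


def _m_state(value: float, threshold: float) -> int:
    """-1 / 0 / +1: monoallelic toward Mat / biallelic / toward Pat."""
    if value > threshold:
        return 1
    if value < -threshold:
        return -1
    return 0


def poo_classify(records: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Classify phased loci into the five parent-of-origin categories.

    Using ``m(x) = sign(x) if |x| > threshold else 0`` on ``poo_ct`` and
    ``poo_kd`` (|x| exactly equal to the threshold is biallelic):

    ========================  =====================
    (m_ct, m_kd)              category
    ========================  =====================
    (0, 0)                    biallelic_stable
    (s, s), s != 0            monoallelic_stable
    (s, 0), s != 0            loss_of_monoallelic
    (0, s), s != 0            gain_of_monoallelic
    (s, -s), s != 0           allelic_flip
    ========================  =====================

    The partition is exhaustive and mutually exclusive. ``biased_parent``
    records the biased allele per condition where applicable.
    """
    if not {"poo_ct", "poo_kd"} <= set(records.columns):
        raise ValueError("records must carry poo_ct and poo_kd")
    cats, biased = [], []
    for ct, kd in zip(records["poo_ct"], records["poo_kd"]):
        m_ct, m_kd = _m_state(ct, threshold), _m_state(kd, threshold)
        name = {1: "paternal", -1: "maternal", 0: None}
        if m_ct == 0 and m_kd == 0:
            cats.append("biallelic_stable")
            biased.append(None)
        elif m_ct == m_kd:
            cats.append("monoallelic_stable")
            biased.append(name[m_ct])
        elif m_kd == 0:
            cats.append("loss_of_monoallelic")
            biased.append(name[m_ct])
        elif m_ct == 0:
            cats.append("gain_of_monoallelic")
            biased.append(name[m_kd])
        else:
            cats.append("allelic_flip")
            biased.append(f"{name[m_ct]}_to_{name[m_kd]}")
    out = records.copy()
    out["category"] = cats
    out["biased_parent"] = biased
    return out


def parental_contribution_delta(
    records: pd.DataFrame, bin_width: float = 10.0
) -> pd.DataFrame:
    """KD - CT difference of the (%Mat - %Pat) frequency distributions.

    Per locus and sample, ``%Mat - %Pat = -100 * poo`` (range -100..+100).
    Both samples are histogrammed on the same grid, normalized to relative
    frequencies, and the bin-wise difference KD - CT is returned.
    """
    n_side = int(round(100 / bin_width))
    centers = np.arange(-n_side, n_side + 1) * bin_width
    out = {"center": centers}
    freqs = {}
    for cond in ("ct", "kd"):
        vals = -100.0 * records[f"poo_{cond}"].to_numpy(dtype=float)
        idx = np.clip(np.round(vals / bin_width).astype(int) + n_side, 0, len(centers) - 1)
        f = np.bincount(idx, minlength=len(centers)).astype(float)
        freqs[cond] = f / f.sum() if f.sum() else f
        out[f"freq_{cond}"] = freqs[cond]
    out["delta_kd_minus_ct"] = freqs["kd"] - freqs["ct"]
    return pd.DataFrame(out)


def cpg_in_motif(read_seq: str, motif_start: int, motif_end: int) -> tuple[int, int]:
    """CpG ("CG") dinucleotide counts inside vs outside a motif span.

    ``motif_start``/``motif_end`` are offsets within ``read_seq``. A CG
    straddling the motif boundary is split across the partition and counts
    in neither tally.
    """
    if not 0 <= motif_start < motif_end <= len(read_seq):
        raise ValueError("motif span must lie within the read")
    inside = read_seq[motif_start:motif_end].count("CG")
    outside = read_seq[:motif_start].count("CG") + read_seq[motif_end:].count("CG")
    return inside, outside
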