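"""Expression and translation calls from count tables.

A gene counts as truly expressed in a library when it has at least
``min_read_count`` reads (default 10) and at least the active RPKM
threshold (0.1 or 1.0, both used in practice).  The translation ratio
(TR) of a gene is its translating-mRNA (RNC) RPKM over its total mRNA
RPKM, a library-size-invariant proxy for translation initiation
efficiency.  Cross-sample detection patterns, per-chromosome enrichment
(Fisher exact) and ribosome-footprint coverage of predicted CDS regions
round out the module.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .io import ExpressionRecord
from .orfs import OrfCandidate
from .statistics import fisher_exact_2x2, ks_two_sample  # noqa: F401  (re-exported)


def compute_rpkm(read_count: int, transcript_len_nt: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_len_nt <= 0 or total_mapped_reads <= 0:
        raise ValueError("transcript length and total mapped reads must be positive")
    return read_count * 1e9 / (transcript_len_nt * total_mapped_reads)


def is_true_expression(record: ExpressionRecord, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """True expression: read count >= 10 AND RPKM >= the active threshold."""
    if math.isnan(record.rpkm):
        raise ValueError(f"record {record.gene_id}/{record.sample_id} lacks rpkm")
    return (
        record.read_count >= config.min_read_count
        and record.rpkm >= config.active_rpkm_threshold
    )


def compute_tr(rnc_rpkm: float, mrna_rpkm: float) -> float:
    """Translation ratio = RNC RPKM / mRNA RPKM; undefined when mRNA RPKM is 0."""
    if mrna_rpkm <= 0:
        raise ValueError("TR undefined for mrna_rpkm <= 0")
    return rnc_rpkm / mrna_rpkm


@dataclass
class TranslationProfile:
    """Per-gene expression/translation summary for one sample."""

    gene_id: str
    mrna_rpkm: float
    rnc_rpkm: float
    tr: float | None
    detected_mrna: bool
    detected_rnc: bool


def translation_profiles(
    records: list[ExpressionRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Pair mRNA and RNC records per (gene, sample) into TR profiles.

    Genes with zero mRNA RPKM have TR flagged undefined (NaN) and are
    excluded from distribution summaries downstream.
    """
    by_key: dict[tuple[str, str], dict[str, ExpressionRecord]] = {}
    for r in records:
        if r.library in ("mRNA", "RNC"):
            by_key.setdefault((r.gene_id, r.sample_id), {})[r.library] = r
    rows = []
    for (gene, sample), libs in sorted(by_key.items()):
        if "mRNA" not in libs or "RNC" not in libs:
            continue
        m, c = libs["mRNA"], libs["RNC"]
        tr = compute_tr(c.rpkm, m.rpkm) if m.rpkm > 0 else float("nan")
        rows.append(
            {
                "gene_id": gene,
                "sample_id": sample,
                "mrna_rpkm": m.rpkm,
                "rnc_rpkm": c.rpkm,
                "tr": tr,
                "detected_mrna": is_true_expression(m, config),
                "detected_rnc": is_true_expression(c, config),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PatternMatrix:
    """Binary genes x samples detection matrix with per-gene class labels."""

    matrix: pd.DataFrame  # index gene_id, columns sample_id, values {0, 1}
    gene_class: pd.Series  # {"ubiquitous", "cell_specific"}


def detection_pattern(
    records: list[ExpressionRecord],
    rpkm_threshold: float | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PatternMatrix:
    """Cross-sample detection matrix at the given RPKM threshold.

    A gene detected in at least ``ubiquity_min_samples`` samples is
    ubiquitous, otherwise cell-specific.
    """
    if rpkm_threshold is not None:
        config = dataclasses.replace(config, active_rpkm_threshold=rpkm_threshold)
    genes = sorted({r.gene_id for r in records})
    samples = sorted({r.sample_id for r in records})
    matrix = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for r in records:
        if is_true_expression(r, config):
            matrix.loc[r.gene_id, r.sample_id] = 1
    row_sums = matrix.sum(axis=1)
    gene_class = pd.Series(
        np.where(row_sums >= config.ubiquity_min_samples, "ubiquitous", "cell_specific"),
        index=matrix.index,
    )
    return PatternMatrix(matrix, gene_class)


def chromosome_enrichment(
    new_gene_chroms: dict[str, str],
    background_gene_chroms: dict[str, str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-chromosome Fisher-exact enrichment of a gene set vs background.

    For each chromosome the 2x2 table is (new on chrom, new elsewhere,
    background on chrom, background elsewhere).  Raw two-sided p-values by
    default; Benjamini-Hochberg q-values optionally appended.
    """
    bg_chroms = set(background_gene_chroms.values())
    missing = sorted(set(new_gene_chroms.values()) - bg_chroms)
    if missing:
        raise ValueError(f"chromosomes absent from background: {missing}")
    n_new = len(new_gene_chroms)
    n_bg = len(background_gene_chroms)
    rows = []
    for chrom in sorted(bg_chroms):
        a = sum(1 for c in new_gene_chroms.values() if c == chrom)
        b = n_new - a
        c = sum(1 for x in background_gene_chroms.values() if x == chrom)
        d = n_bg - c
        rows.append({"chromosome": chrom, "n_new": a, "n_background": c,
                     "p_value": fisher_exact_2x2(a, b, c, d)})
    df = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def rfp_coverage(
    orf: OrfCandidate,
    footprint_intervals: list[tuple[int, int]],
    transcript_len: int | None = None,
) -> tuple[float, float]:
    """Footprint coverage of a predicted CDS.

    Returns (fraction of CDS positions covered by at least one footprint,
    footprint-start density inside the CDS over density outside).  Interval
    coordinates are 0-based half-open on the transcript.  With no
    footprint starts outside the CDS the ratio is reported as inf; with no
    footprints at all, (0, nan).
    """
    cds_len = orf.end_nt - orf.start_nt
    if not footprint_intervals:
        return 0.0, float("nan")
    if transcript_len is None:
        transcript_len = max(e for _, e in footprint_intervals)
    transcript_len = max(transcript_len, orf.end_nt)
    covered = np.zeros(cds_len, dtype=bool)
    starts_inside = 0
    starts_outside = 0
    for s, e in footprint_intervals:
        lo = max(s, orf.start_nt) - orf.start_nt
        hi = min(e, orf.end_nt) - orf.start_nt
        if hi > lo:
            covered[lo:hi] = True
        if orf.start_nt <= s < orf.end_nt:
            starts_inside += 1
        else:
            starts_outside += 1
    fraction = covered.mean() if cds_len else 0.0
    outside_len = transcript_len - cds_len
    density_inside = starts_inside / cds_len if cds_len else 0.0
    if starts_outside == 0 or outside_len <= 0:
        ratio = float("inf") if starts_inside else float("nan")
    else:
        ratio = density_inside / (starts_outside / outside_len)
    return float(fraction), ratio
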