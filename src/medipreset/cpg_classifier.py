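"""Promoter CpG-density classification (HCP / ICP / LCP).

A promoter is scanned with 500-bp windows over the span −700 bp to +200 bp
around its TSS:

* **HCP** — some window has GC fraction ≥ 0.55 *and* CpG observed/expected
  ratio ≥ 0.6;
* **LCP** — no window reaches CpG O/E ≥ 0.4;
* **ICP** — everything else.

CpG O/E is (#CpG × window length) / (#C × #G), defined as 0 when the window
has no C or no G. ``N`` bases count toward window length but not toward
C/G/CpG counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .array_model import PromoterTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpgWindowStats:
    window_start: int
    gc_fraction: float
    cpg_oe: float
    length: int


@dataclass(frozen=True)
class PromoterClassParams:
    """Window definitions and thresholds for the three promoter classes."""

    window_bp: int = 500
    scan_start_rel_tss: int = -700
    scan_end_rel_tss: int = 200
    hcp_gc: float = 0.55
    hcp_oe: float = 0.6
    lcp_oe: float = 0.4
    step_bp: int = 1


def window_stats(seq: str, start: int, length: int = 500) -> CpgWindowStats:
    """GC fraction and CpG O/E of ``seq[start:start+length]``."""
    if start < 0 or start + length > len(seq):
        raise ValueError(
            f"window [{start}, {start + length}) outside sequence of "
            f"length {len(seq)}"
        )
    window = seq[start : start + length].upper()
    c = window.count("C")
    g = window.count("G")
    cpg = window.count("CG")
    gc_fraction = (c + g) / length
    cpg_oe = (cpg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return CpgWindowStats(start, gc_fraction, cpg_oe, length)


def classify_promoter(
    seq: str,
    tss_offset: int,
    params: PromoterClassParams | None = None,
) -> str:
    """Classify one promoter sequence (transcription orientation).

    ``tss_offset`` is the 0-based index of the TSS within ``seq``. Windows
    of ``window_bp`` start at every ``step_bp`` position such that the
    window lies fully inside [tss−700, tss+200). Returns one of
    HCP/ICP/LCP, or UNCLASSIFIED when the sequence does not cover the scan
    span.
    """
    params = params or PromoterClassParams()
    scan_start = tss_offset + params.scan_start_rel_tss
    scan_end = tss_offset + params.scan_end_rel_tss
    last_start = scan_end - params.window_bp
    if scan_start < 0 or scan_end > len(seq) or last_start < scan_start:
        logger.warning(
            "sequence (len %d, TSS at %d) does not cover the %d..%d scan "
            "span; promoter left UNCLASSIFIED",
            len(seq), tss_offset, scan_start, scan_end,
        )
        return "UNCLASSIFIED"

    any_oe_mid = False
    for start in range(scan_start, last_start + 1, params.step_bp):
        st = window_stats(seq, start, params.window_bp)
        if st.gc_fraction >= params.hcp_gc and st.cpg_oe >= params.hcp_oe:
            return "HCP"
        if st.cpg_oe >= params.lcp_oe:
            any_oe_mid = True
    return "ICP" if any_oe_mid else "LCP"


def _oriented_region(record_seq: str, region_start: int, region_end: int, strand: str) -> str:
    sub = record_seq[region_start:region_end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def classify_all(
    fasta_path: str | Path,
    promoters: PromoterTable,
    params: PromoterClassParams | None = None,
) -> PromoterTable:
    """Classify every promoter from a FASTA file.

    FASTA records may be keyed by ``promoter_id`` (record = the 1,800-bp
    promoter region in transcription orientation, TSS at offset 1,300) or
    by chromosome (the region is extracted by coordinate and
    reverse-complemented for − strand promoters). Promoters without
    sequence are left UNCLASSIFIED and counted in the log.
    """
    params = params or PromoterClassParams()
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    classes = {}
    missing = 0
    for promoter_id, row in promoters.df.iterrows():
        if promoter_id in records:
            seq = records[promoter_id]
            tss_offset = 1300
        elif row["chrom"] in records:
            seq = _oriented_region(
                records[row["chrom"]],
                int(row["region_start"]),
                int(row["region_end"]),
                row["strand"],
            )
            tss_offset = 1300
        else:
            missing += 1
            classes[promoter_id] = "UNCLASSIFIED"
            continue
        classes[promoter_id] = classify_promoter(seq, tss_offset, params)

    if missing:
        logger.warning("%d promoter(s) had no sequence; left UNCLASSIFIED", missing)
    series = pd.Series(classes)
    counts = series.value_counts().to_dict()
    logger.info("promoter class counts: %s", counts)
    return promoters.with_classes(series)
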