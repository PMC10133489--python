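"""DMR tabulation and reset-gene classification across diet comparisons.

The study design yields three comparisons: mLP-CN vs mCN-CN (the baseline
effect of maternal protein restriction under a normal postnatal diet),
mLP-LP vs mLP-CN (postnatal low-protein intervention) and mLP-HP vs mLP-CN
(postnatal high-protein intervention). A gene with a baseline DMR is
"reset" by a postnatal diet when that comparison shows a DMR of opposite
direction (PeakDM sign reversal), giving six categories:
{hyper, hypo} × {both, LP_only, HP_only}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .array_model import PromoterTable, SampleSheet, SignalMatrix
from .peak_caller import KsConfig, Peak, call_dmrs

logger = logging.getLogger(__name__)

#: The three preconfigured comparisons, in presentation order.
COMPARISONS = (
    ("mLP-CN vs mCN-CN", "mLP-CN", "mCN-CN"),
    ("mLP-LP vs mLP-CN", "mLP-LP", "mLP-CN"),
    ("mLP-HP vs mLP-CN", "mLP-HP", "mLP-CN"),
)

RESET_CATEGORIES = ("both", "LP_only", "HP_only", "none")


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    group_a: str
    group_b: str


@dataclass
class ResetRecord:
    """Per-gene reset classification across the three comparisons."""

    gene_symbol: str
    promoter_id: str
    baseline_direction: str  # hyper / hypo
    reset_by: str            # both / LP_only / HP_only / none
    peak_dm_baseline: float
    peak_dm_lp: float | None
    peak_dm_hp: float | None
    ambiguous: bool = False
    complete: bool | None = None


# ---------------------------------------------------------------------------
# Counting (Table-1 style)
# ---------------------------------------------------------------------------

def count_dmrs(
    dmrs_by_comparison: dict[str, Sequence[Peak]],
    promoters: PromoterTable,
    unit: str = "peak",
) -> pd.DataFrame:
    """Tabulate hyper/hypo/total DMR counts, overall and per promoter class.

    ``unit='peak'`` counts every merged peak (a promoter may contribute
    more than one); ``unit='promoter'`` counts each (promoter, direction)
    once.
    """
    if unit not in ("peak", "promoter"):
        raise ValueError(f"unknown counting unit {unit!r}")
    rows = []
    for comparison, dmrs in dmrs_by_comparison.items():
        seen: set[tuple[str, str]] = set()
        counts = {
            d: {c: 0 for c in ("all_regions", "HCP", "ICP", "LCP", "UNCLASSIFIED")}
            for d in ("hyper", "hypo")
        }
        for pk in dmrs:
            if unit == "promoter":
                key = (pk.promoter_id, pk.direction)
                if key in seen:
                    continue
                seen.add(key)
            cls = (
                promoters.cpg_class(pk.promoter_id)
                if pk.promoter_id in promoters
                else "UNCLASSIFIED"
            )
            counts[pk.direction]["all_regions"] += 1
            counts[pk.direction][cls] += 1
        for direction in ("hyper", "hypo"):
            rows.append((comparison, direction, *counts[direction].values()))
        rows.append(
            (
                comparison,
                "total",
                *(
                    counts["hyper"][c] + counts["hypo"][c]
                    for c in ("all_regions", "HCP", "ICP", "LCP", "UNCLASSIFIED")
                ),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["comparison", "direction", "all_regions", "HCP", "ICP",
                 "LCP", "UNCLASSIFIED"],
    )


# ---------------------------------------------------------------------------
# Reset classification
# ---------------------------------------------------------------------------

def classify_reset_values(
    baseline: float, lp: float | None, hp: float | None
) -> tuple[str, str]:
    """Sign-reversal rule on per-gene PeakDM values.

    Returns (baseline_direction, category). A postnatal comparison resets
    the gene iff its PeakDM is present and of opposite sign to the
    baseline PeakDM; same-direction or absent values do not.
    """
    if baseline == 0:
        raise ValueError("baseline PeakDM of 0 has no direction")
    direction = "hyper" if baseline > 0 else "hypo"
    flip = lambda v: v is not None and not np.isnan(v) and v * baseline < 0
    reset_lp, reset_hp = flip(lp), flip(hp)
    if reset_lp and reset_hp:
        cat = "both"
    elif reset_lp:
        cat = "LP_only"
    elif reset_hp:
        cat = "HP_only"
    else:
        cat = "none"
    return direction, cat


def _representative(peaks: Iterable[Peak]) -> Peak:
    """The peak with maximal |PeakDM| stands for the promoter."""
    return max(peaks, key=lambda p: (abs(p.peak_dm), p.promoter_id))


def classify_reset(
    baseline: Sequence[Peak],
    lp: Sequence[Peak],
    hp: Sequence[Peak],
    promoters: PromoterTable | None = None,
) -> list[ResetRecord]:
    """Classify every gene with a baseline DMR into a reset category.

    Genes whose baseline DMRs conflict in direction are flagged ambiguous
    and excluded from the categories. Within a comparison, a promoter with
    several peaks is represented by the peak of maximal |PeakDM|.
    """
    def by_promoter(peaks: Sequence[Peak]) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for pk in peaks:
            out.setdefault(pk.promoter_id, []).append(pk)
        return out

    base_map = by_promoter(baseline)
    lp_map = by_promoter(lp)
    hp_map = by_promoter(hp)

    records = []
    for promoter_id in sorted(base_map):
        peaks = base_map[promoter_id]
        gene = (
            promoters.gene_symbol(promoter_id)
            if promoters is not None and promoter_id in promoters
            else promoter_id
        )
        directions = {pk.direction for pk in peaks}
        if len(directions) > 1:
            logger.warning(
                "promoter %s has baseline DMRs of conflicting direction; "
                "flagged ambiguous", promoter_id,
            )
            rep = _representative(peaks)
            records.append(
                ResetRecord(gene, promoter_id, rep.direction, "none",
                            rep.peak_dm, None, None, ambiguous=True)
            )
            continue
        rep = _representative(peaks)
        lp_dm = (
            _representative(lp_map[promoter_id]).peak_dm
            if promoter_id in lp_map else None
        )
        hp_dm = (
            _representative(hp_map[promoter_id]).peak_dm
            if promoter_id in hp_map else None
        )
        direction, category = classify_reset_values(rep.peak_dm, lp_dm, hp_dm)
        records.append(
            ResetRecord(gene, promoter_id, direction, category,
                        rep.peak_dm, lp_dm, hp_dm)
        )
    return records


def completeness_check(
    signal: SignalMatrix,
    samples: SampleSheet,
    records: Sequence[ResetRecord],
    cfg: KsConfig | None = None,
    promoters: PromoterTable | None = None,
    design=None,
) -> list[ResetRecord]:
    """Verify that reset genes returned all the way to the control level.

    For every gene reset by diet D, the comparison mLP-D vs mCN-CN is
    examined at that promoter: the reset is *complete* when no DMR is
    called there for any resetting diet. Genes with category ``none`` keep
    ``complete=None``.
    """
    cfg = cfg or KsConfig()
    check_dmrs = {
        "LP": call_dmrs(signal, samples, "mLP-LP", "mCN-CN", cfg, promoters, design),
        "HP": call_dmrs(signal, samples, "mLP-HP", "mCN-CN", cfg, promoters, design),
    }
    flagged = {
        diet: {pk.promoter_id for pk in dmrs} for diet, dmrs in check_dmrs.items()
    }
    out = []
    for rec in records:
        diets = {"both": ("LP", "HP"), "LP_only": ("LP",), "HP_only": ("HP",)}.get(
            rec.reset_by
        )
        complete = (
            None if diets is None
            else all(rec.promoter_id not in flagged[d] for d in diets)
        )
        out.append(
            ResetRecord(rec.gene_symbol, rec.promoter_id, rec.baseline_direction,
                        rec.reset_by, rec.peak_dm_baseline, rec.peak_dm_lp,
                        rec.peak_dm_hp, rec.ambiguous, complete)
        )
    return out


def summarize_reset(records: Sequence[ResetRecord]) -> pd.DataFrame:
    """Counts per {hyper, hypo} × {both, LP_only, HP_only} plus the total.

    Ambiguous records and category ``none`` are excluded from the total
    (they are not reset genes).
    """
    table = pd.DataFrame(
        0,
        index=["hyper", "hypo"],
        columns=["both", "LP_only", "HP_only"],
    )
    for rec in records:
        if rec.ambiguous or rec.reset_by == "none":
            continue
        table.loc[rec.baseline_direction, rec.reset_by] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def records_to_frame(records: Sequence[ResetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_symbol, r.promoter_id, r.baseline_direction, r.reset_by,
             r.peak_dm_baseline, r.peak_dm_lp, r.peak_dm_hp, r.ambiguous,
             r.complete)
            for r in records
        ],
        columns=["gene_symbol", "promoter_id", "baseline_direction", "reset_by",
                 "peak_dm_baseline", "peak_dm_lp", "peak_dm_hp", "ambiguous",
                 "complete"],
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """Published per-comparison DMR count table (internal-consistency fixture)."""
    with resources.files("medipreset.fixtures").joinpath("table1_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table2_fixture() -> pd.DataFrame:
    """Published 34-gene reset table with PeakDM values per comparison.

    Two rows (Mapt, Sp7) are printed with a positive baseline PeakDM and no
    sign reversal despite being listed as hypomethylated resets; they carry
    ``anomalous=1`` and are excluded from sign-rule consistency checks.
    """
    with resources.files("medipreset.fixtures").joinpath("table2_peakdm.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_reset_fixture(table2: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply the sign-reversal rule to the published PeakDM table.

    Returns the fixture with ``baseline_direction`` and ``reset_by``
    columns computed from the printed values.
    """
    df = (table2 if table2 is not None else load_table2_fixture()).copy()
    dirs, cats = [], []
    for _, row in df.iterrows():
        lp = None if pd.isna(row["peakdm_lp"]) else float(row["peakdm_lp"])
        hp = None if pd.isna(row["peakdm_hp"]) else float(row["peakdm_hp"])
        d, c = classify_reset_values(float(row["peakdm_baseline"]), lp, hp)
        dirs.append(d)
        cats.append(c)
    df["baseline_direction"] = dirs
    df["reset_by"] = cats
    return df
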