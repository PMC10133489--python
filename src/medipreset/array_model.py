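"""Core data types for the promoter tiling array and on-disk format I/O.

The array tiles promoter regions (−1,300 bp to +500 bp around each TSS,
~210 bp probe spacing) of a RefSeq promoter set. All internal coordinates
are 0-based half-open; the 1-based TSS column of ``promoters.tsv`` is
converted at the boundary.

On-disk schemas (TSV, header row required):

* ``design.tsv``:     probe_id, chrom, start, end, promoter_id
* ``promoters.tsv``:  promoter_id, gene_symbol, chrom, tss, strand
* ``intensities.tsv``: long format sample_id, probe_id, ip, input
* ``samples.tsv``:    sample_id, group, replicate
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM_BP = 1300
PROMOTER_DOWNSTREAM_BP = 500
PROMOTER_REGION_BP = PROMOTER_UPSTREAM_BP + PROMOTER_DOWNSTREAM_BP

#: CpG-density promoter classes (UNCLASSIFIED until sequence is supplied).
CPG_CLASSES = ("HCP", "ICP", "LCP", "UNCLASSIFIED")

#: The six diet groups: maternal diet (mCN/mLP) x offspring diet (CN/LP/HP).
PAPER_GROUPS = ("mCN-CN", "mLP-CN", "mCN-LP", "mLP-LP", "mCN-HP", "mLP-HP")

SIGNAL_STAGES = ("raw_log2", "median_centered", "quantile_normalized", "smoothed")


class ArrayModelError(ValueError):
    """Raised for malformed or inconsistent array inputs."""


@dataclass(frozen=True)
class Probe:
    """A single strandless array probe tied to one promoter."""

    probe_id: str
    chrom: str
    start: int
    end: int
    promoter_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ArrayModelError(
                f"probe {self.probe_id!r}: degenerate interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def promoter_region(tss: int, strand: str) -> tuple[int, int]:
    """0-based half-open promoter region for a 1-based TSS coordinate.

    The region spans −1,300 bp to +500 bp of the TSS in transcription
    orientation: ``[tss-1300, tss+500)`` on '+', ``[tss-500, tss+1300)``
    on '−'; either way it is exactly 1,800 bp.
    """
    if strand == "+":
        return tss - PROMOTER_UPSTREAM_BP, tss + PROMOTER_DOWNSTREAM_BP
    if strand in ("-", "−"):
        return tss - PROMOTER_DOWNSTREAM_BP, tss + PROMOTER_UPSTREAM_BP
    raise ArrayModelError(f"unknown strand {strand!r}")


@dataclass
class PromoterTable:
    """Promoter annotation backed by a DataFrame indexed by promoter_id.

    Columns: gene_symbol, chrom, tss (1-based), strand, region_start,
    region_end (0-based half-open), cpg_class.
    """

    df: pd.DataFrame

    REQUIRED = ("gene_symbol", "chrom", "tss", "strand")

    @classmethod
    def from_frame(cls, raw: pd.DataFrame) -> "PromoterTable":
        missing = [c for c in ("promoter_id", *cls.REQUIRED) if c not in raw.columns]
        if missing:
            raise ArrayModelError(f"promoter table missing columns: {missing}")
        if raw["promoter_id"].duplicated().any():
            dups = raw.loc[raw["promoter_id"].duplicated(), "promoter_id"].tolist()
            raise ArrayModelError(f"duplicate promoter_id(s): {dups[:5]}")
        df = raw.set_index("promoter_id").copy()
        df["strand"] = df["strand"].replace("−", "-")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ArrayModelError(
                f"bad strand for promoter(s) {df.index[bad].tolist()[:5]}"
            )
        regions = [
            promoter_region(int(t), s) for t, s in zip(df["tss"], df["strand"])
        ]
        df["region_start"] = [r[0] for r in regions]
        df["region_end"] = [r[1] for r in regions]
        if "cpg_class" not in df.columns:
            df["cpg_class"] = "UNCLASSIFIED"
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, promoter_id: str) -> bool:
        return promoter_id in self.df.index

    def gene_symbol(self, promoter_id: str) -> str:
        return str(self.df.at[promoter_id, "gene_symbol"])

    def cpg_class(self, promoter_id: str) -> str:
        return str(self.df.at[promoter_id, "cpg_class"])

    def with_classes(self, classes: pd.Series) -> "PromoterTable":
        df = self.df.copy()
        df.loc[classes.index, "cpg_class"] = classes
        return PromoterTable(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.reset_index()
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Sample → diet-group assignment."""

    df: pd.DataFrame  # index sample_id; columns group, replicate

    @classmethod
    def from_frame(cls, raw: pd.DataFrame) -> "SampleSheet":
        for col in ("sample_id", "group"):
            if col not in raw.columns:
                raise ArrayModelError(f"sample sheet missing column {col!r}")
        if raw["sample_id"].duplicated().any():
            raise ArrayModelError("duplicate sample_id in sample sheet")
        df = raw.set_index("sample_id").copy()
        if "replicate" not in df.columns:
            df["replicate"] = np.arange(1, len(df) + 1)
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def samples_in(self, group: str) -> list[str]:
        hits = self.df.index[self.df["group"] == group].tolist()
        if not hits:
            raise ArrayModelError(f"group {group!r} has no samples")
        return hits

    def to_tsv(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class IntensityTable:
    """Two-channel probe intensities: IP (MeDIP) and input, probes × samples.

    Both frames share index (probe_id, in design order) and columns
    (sample_id). All intensities are strictly positive.
    """

    ip: pd.DataFrame
    input: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ip.index.equals(self.input.index) or not self.ip.columns.equals(
            self.input.columns
        ):
            raise ArrayModelError("ip/input frames are not aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ip.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write the long-format intensities.tsv schema."""
        long = pd.concat(
            {
                "ip": self.ip.stack(),
                "input": self.input.stack(),
            },
            axis=1,
        )
        long.index.names = ["probe_id", "sample_id"]
        long = long.reset_index()[["sample_id", "probe_id", "ip", "input"]]
        long.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class SignalMatrix:
    """Probes × samples matrix of log2(IP/input) ratios plus a stage tag.

    ``stage`` advances monotonically through the preprocessing chain:
    raw_log2 → median_centered → quantile_normalized → smoothed.
    """

    values: pd.DataFrame  # index probe_id (design order), columns sample_id
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in SIGNAL_STAGES:
            raise ArrayModelError(f"unknown stage {self.stage!r}")
        if self.values.isna().any().any():
            raise ArrayModelError("SignalMatrix contains missing values")

    def advanced(self, values: pd.DataFrame, stage: str) -> "SignalMatrix":
        if SIGNAL_STAGES.index(stage) <= SIGNAL_STAGES.index(self.stage):
            raise ArrayModelError(
                f"stage must advance: {self.stage} -> {stage} is not allowed"
            )
        return SignalMatrix(values, stage)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "smoothed") -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(df, stage)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_design(
    design_path: str | Path, promoter_path: str | Path
) -> tuple[list[Probe], PromoterTable]:
    """Load and cross-validate the probe layout and promoter annotation.

    Probes are returned sorted by (chrom, start). Duplicate probe ids and
    probes referencing unknown promoters are hard errors.
    """
    ddf = pd.read_csv(design_path, sep="\t", dtype={"chrom": str})
    missing = [
        c for c in ("probe_id", "chrom", "start", "end", "promoter_id")
        if c not in ddf.columns
    ]
    if missing:
        raise ArrayModelError(f"design missing columns: {missing}")
    if ddf["probe_id"].duplicated().any():
        dups = ddf.loc[ddf["probe_id"].duplicated(), "probe_id"].tolist()
        raise ArrayModelError(f"duplicate probe_id(s): {dups[:5]}")

    promoters = PromoterTable.from_frame(pd.read_csv(promoter_path, sep="\t"))

    unknown = ~ddf["promoter_id"].isin(promoters.df.index)
    if unknown.any():
        bad = ddf.loc[unknown, ["probe_id", "promoter_id"]].iloc[0]
        raise ArrayModelError(
            f"probe {bad['probe_id']!r} references unknown promoter "
            f"{bad['promoter_id']!r}"
        )

    ddf = ddf.sort_values(["chrom", "start"], kind="mergesort")
    probes = [
        Probe(str(r.probe_id), str(r.chrom), int(r.start), int(r.end),
              str(r.promoter_id))
        for r in ddf.itertuples(index=False)
    ]
    return probes, promoters


def write_design(probes: Sequence[Probe], path: str | Path) -> None:
    pd.DataFrame(
        [
            (p.probe_id, p.chrom, p.start, p.end, p.promoter_id)
            for p in probes
        ],
        columns=["probe_id", "chrom", "start", "end", "promoter_id"],
    ).to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> SampleSheet:
    return SampleSheet.from_frame(pd.read_csv(path, sep="\t"))


def read_intensities(
    path: str | Path, design: Sequence[Probe]
) -> IntensityTable:
    """Load long-format two-channel intensities and validate completeness.

    The probe set must equal the design probe set for every sample; zero or
    negative intensities are rejected (log2 undefined).
    """
    long = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "probe_id", "ip", "input") if c not in long.columns]
    if missing:
        raise ArrayModelError(f"intensities missing columns: {missing}")

    bad = long[(long["ip"] <= 0) | (long["input"] <= 0)]
    if len(bad):
        row = bad.iloc[0]
        raise ArrayModelError(
            f"non-positive intensity for probe {row['probe_id']!r} in sample "
            f"{row['sample_id']!r} (ip={row['ip']}, input={row['input']})"
        )
    dup = long.duplicated(["sample_id", "probe_id"])
    if dup.any():
        row = long[dup].iloc[0]
        raise ArrayModelError(
            f"duplicate intensity row for probe {row['probe_id']!r}, sample "
            f"{row['sample_id']!r}"
        )

    probe_order = [p.probe_id for p in design]
    design_set = set(probe_order)
    ip = long.pivot(index="probe_id", columns="sample_id", values="ip")
    inp = long.pivot(index="probe_id", columns="sample_id", values="input")

    file_set = set(ip.index)
    if file_set != design_set:
        lost = sorted(design_set - file_set)[:5]
        extra = sorted(file_set - design_set)[:5]
        raise ArrayModelError(
            f"probe set mismatch vs design (missing {lost}, unexpected {extra})"
        )
    if ip.isna().any().any() or inp.isna().any().any():
        na = ip.isna() | inp.isna()
        probe = na.index[na.any(axis=1)][0]
        raise ArrayModelError(f"incomplete intensities for probe {probe!r}")

    ip = ip.loc[probe_order]
    inp = inp.loc[probe_order]
    return IntensityTable(ip.astype(float), inp.astype(float))


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def bed_score(score: float) -> int:
    """Map a peak score onto the BED 0–1000 score column."""
    return min(1000, round(100 * score))


def write_bed(
    regions: Iterable,
    path: str | Path,
    track_name: str = "medipreset_peaks",
) -> None:
    """Write peaks/DMRs as BED6 with score = min(1000, round(100·max_pscore)).

    Regions need chrom/start/end plus ``max_pscore`` and a name
    (``promoter_id`` or ``name``). Chromosomes are written in lexical order.
    """
    rows = []
    for r in regions:
        name = getattr(r, "promoter_id", None) or getattr(r, "name", ".")
        score = getattr(r, "max_pscore", 0.0)
        strand = getattr(r, "strand", ".")
        rows.append((r.chrom, int(r.start), int(r.end), name, bed_score(score), strand))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read back BED6 written by :func:`write_bed` (track line skipped)."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("track")]
    if not lines:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
    from io import StringIO

    return pd.read_csv(
        StringIO("".join(lines)),
        sep="\t",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
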