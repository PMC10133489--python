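"""Sliding-window one-sided Kolmogorov–Smirnov peak and DMR calling.

Each probe receives a −log10 p-score from a one-sided two-sample KS test
asking whether probes in the 1,500-bp window around it are drawn from a
more positive distribution of log2 ratios than the rest of the array.
Runs of ≥2 adjacent probes with p-score ≥ 2 become peaks; peaks within
500 bp of each other are merged. For group comparisons the test runs on
the per-probe difference of group means (hypermethylation in group A) and
on its negation (hypomethylation), and each peak is summarized by its
PeakDM value — the mean differential log2 ratio over member probes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .array_model import Probe, PromoterTable, SampleSheet, SignalMatrix

logger = logging.getLogger(__name__)

PSCORE_CAP = 300.0


@dataclass(frozen=True)
class KsConfig:
    """Peak-calling parameters (defaults follow the NimbleScan procedure)."""

    window_bp: int = 1500
    pscore_cutoff: float = 2.0
    min_probes_above: int = 2
    merge_gap_bp: int = 500
    rest_mode: str = "exclude_window"  # or "whole_array"
    peak_dm_summary: str = "mean"  # or "max"

    def __post_init__(self) -> None:
        if self.rest_mode not in ("exclude_window", "whole_array"):
            raise ValueError(f"unknown rest_mode {self.rest_mode!r}")
        if self.peak_dm_summary not in ("mean", "max"):
            raise ValueError(f"unknown peak_dm_summary {self.peak_dm_summary!r}")


@dataclass
class ProbeScoreTrack:
    """Per-probe statistic being tested, sorted by (chrom, midpoint)."""

    probe_ids: list[str]
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    promoter_ids: list[str]

    @classmethod
    def from_design(cls, design: Sequence[Probe], values: np.ndarray) -> "ProbeScoreTrack":
        if len(design) != len(values):
            raise ValueError("one value per probe required")
        return cls(
            probe_ids=[p.probe_id for p in design],
            chroms=np.array([p.chrom for p in design]),
            starts=np.array([p.start for p in design]),
            ends=np.array([p.end for p in design]),
            values=np.asarray(values, dtype=float),
            promoter_ids=[p.promoter_id for p in design],
        )

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def negated(self) -> "ProbeScoreTrack":
        return replace(self, values=-self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Peak:
    """A scored enrichment peak mapped to a promoter."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    max_pscore: float
    peak_dm: float
    promoter_id: str
    direction: str  # "hyper" or "hypo"

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def ks_pscore(window_values: Sequence[float], rest_values: Sequence[float]) -> float:
    """One-sided KS score: −log10 p that the window is shifted positive.

    D⁺ = sup_x [ECDF_rest(x) − ECDF_window(x)] clamped at ≥ 0, and
    p = exp(−2 D⁺² m n / (m + n)) — the standard one-sided large-sample
    bound. The returned −log10 p is capped at 300.
    """
    w = np.sort(np.asarray(window_values, dtype=float))
    r = np.sort(np.asarray(rest_values, dtype=float))
    m, n = len(w), len(r)
    if m < 2 or n < 2:
        raise ValueError("both window and rest need >= 2 values")
    pooled = np.concatenate([w, r])
    pooled.sort()
    ecdf_w = np.searchsorted(w, pooled, side="right") / m
    ecdf_r = np.searchsorted(r, pooled, side="right") / n
    d_plus = max(0.0, float(np.max(ecdf_r - ecdf_w)))
    return _pscore_from_d(d_plus, m, n)


def _pscore_from_d(d_plus: float, m: int, n: int) -> float:
    log_p = -2.0 * d_plus * d_plus * m * n / (m + n)  # natural log of p
    return min(PSCORE_CAP, -log_p / math.log(10.0))


def score_probes(track: ProbeScoreTrack, cfg: KsConfig | None = None) -> np.ndarray:
    """Per-probe −log10 KS p-scores over the sliding window.

    The window around probe *p* contains all probes on the same chromosome
    whose midpoints lie within ±window_bp/2 of *p*'s midpoint; the rest is
    every other probe on the array (``exclude_window``) or the whole array
    (``whole_array``). Probes whose window or rest holds fewer than two
    values score 0.
    """
    cfg = cfg or KsConfig()
    half = cfg.window_bp / 2.0
    n_total = len(track)
    values = track.values
    all_sorted = np.sort(values)
    scores = np.zeros(n_total)

    for chrom in pd.unique(track.chroms):
        idx = np.flatnonzero(track.chroms == chrom)
        mids = track.midpoints[idx]
        left = np.searchsorted(mids, mids - half, side="left")
        right = np.searchsorted(mids, mids + half, side="right")
        for ii in range(len(idx)):
            sel = idx[left[ii] : right[ii]]
            m = len(sel)
            if m < 2:
                logger.debug("probe %s isolated in window; score 0",
                             track.probe_ids[idx[ii]])
                continue
            w = np.sort(values[sel])
            if cfg.rest_mode == "exclude_window":
                n = n_total - m
                if n < 2:
                    continue
                # counts strictly below each window value
                below_all = np.searchsorted(all_sorted, w, side="left")
                below_w = np.searchsorted(w, w, side="left")
                ecdf_r = (below_all - below_w) / n
            else:
                n = n_total
                below_all = np.searchsorted(all_sorted, w, side="left")
                below_w = np.searchsorted(w, w, side="left")
                ecdf_r = below_all / n
            # sup of ECDF_rest − ECDF_window is attained just below a window
            # value (rest ECDF maximal there while the window ECDF has not
            # yet jumped); beyond the largest window value the gap is ≤ 0.
            ecdf_w = below_w / m
            d_plus = max(0.0, float(np.max(ecdf_r - ecdf_w)))
            scores[idx[ii]] = _pscore_from_d(d_plus, m, n)
    return scores


def _merge_peaks(peaks: list[Peak], merge_gap_bp: int) -> list[Peak]:
    """Iteratively merge same-chromosome peaks with gap ≤ merge_gap_bp."""
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: (p.chrom, p.start))
    merged: list[Peak] = [peaks[0]]
    for nxt in peaks[1:]:
        cur = merged[-1]
        if nxt.chrom == cur.chrom and nxt.start - cur.end <= merge_gap_bp:
            merged[-1] = Peak(
                chrom=cur.chrom,
                start=cur.start,
                end=max(cur.end, nxt.end),
                probe_ids=cur.probe_ids + nxt.probe_ids,
                max_pscore=max(cur.max_pscore, nxt.max_pscore),
                peak_dm=float("nan"),  # recomputed by caller
                promoter_id="",
                direction=cur.direction,
            )
        else:
            merged.append(nxt)
    return merged


def call_peaks(
    track: ProbeScoreTrack,
    pscores: np.ndarray,
    cfg: KsConfig | None = None,
    promoters: PromoterTable | None = None,
    direction: str = "hyper",
    dm_values: np.ndarray | None = None,
) -> list[Peak]:
    """Turn per-probe p-scores into merged, scored peaks.

    Maximal runs of track-adjacent probes (same chromosome) with p-score ≥
    cutoff and length ≥ ``min_probes_above`` become peaks; peaks within
    ``merge_gap_bp`` of each other are merged to a fixed point. Each peak
    is assigned to the promoter contributing the most member probes
    (lexicographically smallest on ties) and summarized by its PeakDM value
    over ``dm_values`` (defaults to the track values).
    """
    cfg = cfg or KsConfig()
    if dm_values is None:
        dm_values = track.values
    dm_values = np.asarray(dm_values, dtype=float)

    above = pscores >= cfg.pscore_cutoff
    peaks: list[Peak] = []
    i = 0
    n = len(track)
    probe_index = {pid: k for k, pid in enumerate(track.probe_ids)}
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        # a run extends over consecutive significant probes, but never across
        # a gap wider than the merge distance: separate peaks that far apart
        # would not merge either, so they cannot be one peak
        while (
            j + 1 < n
            and above[j + 1]
            and track.chroms[j + 1] == track.chroms[i]
            and track.starts[j + 1] - track.ends[j] <= cfg.merge_gap_bp
        ):
            j += 1
        if j - i + 1 >= cfg.min_probes_above:
            ids = track.probe_ids[i : j + 1]
            peaks.append(
                Peak(
                    chrom=str(track.chroms[i]),
                    start=int(np.min(track.starts[i : j + 1])),
                    end=int(np.max(track.ends[i : j + 1])),
                    probe_ids=ids,
                    max_pscore=float(np.max(pscores[i : j + 1])),
                    peak_dm=float("nan"),
                    promoter_id="",
                    direction=direction,
                )
            )
        i = j + 1

    # merge to fixed point (single sorted sweep is already a fixed point)
    peaks = _merge_peaks(peaks, cfg.merge_gap_bp)

    out = []
    for pk in peaks:
        rows = [probe_index[pid] for pid in pk.probe_ids]
        member_dm = dm_values[rows]
        if cfg.peak_dm_summary == "mean":
            peak_dm = float(np.mean(member_dm))
        else:
            peak_dm = float(member_dm[np.argmax(np.abs(member_dm))])
        proms = pd.Series([track.promoter_ids[r] for r in rows])
        counts = proms.value_counts()
        best = counts[counts == counts.max()].index.min()
        out.append(replace(pk, peak_dm=peak_dm, promoter_id=str(best)))
    return out


def differential_track(
    signal: SignalMatrix,
    samples: SampleSheet,
    group_a: str,
    group_b: str,
    design: Sequence[Probe],
) -> ProbeScoreTrack:
    """Per-probe mean(group A) − mean(group B) of normalized log2 ratios."""
    a_cols = samples.samples_in(group_a)
    b_cols = samples.samples_in(group_b)
    diff = (
        signal.values[a_cols].mean(axis=1) - signal.values[b_cols].mean(axis=1)
    ).to_numpy()
    return ProbeScoreTrack.from_design(design, diff)


def call_dmrs(
    signal: SignalMatrix,
    samples: SampleSheet,
    group_a: str,
    group_b: str,
    cfg: KsConfig | None = None,
    promoters: PromoterTable | None = None,
    design: Sequence[Probe] | None = None,
) -> list[Peak]:
    """Call hyper- and hypomethylated DMRs of group A relative to group B.

    The one-sided KS scan runs on the differential track (hypermethylated
    peaks, positive PeakDM) and on its negation (hypomethylated peaks,
    negative PeakDM); the union is returned. Peaks whose PeakDM sign
    contradicts their direction (possible for marginal runs straddling
    zero) are dropped with a log message.
    """
    cfg = cfg or KsConfig()
    if design is None:
        raise ValueError("design is required to build the differential track")
    track = differential_track(signal, samples, group_a, group_b, design)

    dmrs: list[Peak] = []
    for direction, t in (("hyper", track), ("hypo", track.negated())):
        scores = score_probes(t, cfg)
        peaks = call_peaks(
            t, scores, cfg, promoters, direction=direction, dm_values=track.values
        )
        for pk in peaks:
            if direction == "hyper" and pk.peak_dm <= 0:
                logger.info("dropping hyper peak with non-positive PeakDM at "
                            "%s:%d-%d", pk.chrom, pk.start, pk.end)
                continue
            if direction == "hypo" and pk.peak_dm >= 0:
                logger.info("dropping hypo peak with non-negative PeakDM at "
                            "%s:%d-%d", pk.chrom, pk.start, pk.end)
                continue
            dmrs.append(pk)
    return dmrs


def peaks_to_frame(peaks: Sequence[Peak], promoters: PromoterTable | None = None) -> pd.DataFrame:
    """Tabulate peaks as the dmrs.tsv schema."""
    rows = []
    for pk in peaks:
        gene = cls = ""
        if promoters is not None and pk.promoter_id in promoters:
            gene = promoters.gene_symbol(pk.promoter_id)
            cls = promoters.cpg_class(pk.promoter_id)
        rows.append(
            (pk.promoter_id, gene, cls, pk.chrom, pk.start, pk.end,
             pk.n_probes, pk.max_pscore, pk.peak_dm, pk.direction)
        )
    return pd.DataFrame(
        rows,
        columns=["promoter_id", "gene_symbol", "cpg_class", "chrom", "start",
                 "end", "n_probes", "max_pscore", "peak_dm", "direction"],
    )
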