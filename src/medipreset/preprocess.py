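"""Two-channel intensity normalization chain.

Converts MeDIP (IP) / input intensity pairs into normalized, smoothed
log2 ratios: log2(IP/input) → per-sample median centering → cross-sample
quantile normalization → positional linear smoothing along each chromosome.
The chain is deterministic and applied jointly to all samples so that
downstream group comparisons are on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .array_model import IntensityTable, Probe, SignalMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Smoothing parameters.

    smoothing_window_bp
        Full width of the positional window centred on each probe midpoint.
        Default 600 bp ≈ 3 probes at the array's ~210 bp spacing.
    smoothing_kind
        ``triangular`` (weights fall linearly with distance) or ``boxcar``
        (uniform weights).
    """

    smoothing_window_bp: int = 600
    smoothing_kind: str = "triangular"

    def __post_init__(self) -> None:
        if self.smoothing_window_bp < 0:
            raise ValueError("smoothing_window_bp must be >= 0")
        if self.smoothing_kind not in ("triangular", "boxcar"):
            raise ValueError(f"unknown smoothing kind {self.smoothing_kind!r}")


def log2_ratio(intensities: IntensityTable) -> SignalMatrix:
    """Per-probe, per-sample log2(IP/input)."""
    values = np.log2(intensities.ip / intensities.input)
    return SignalMatrix(values, "raw_log2")


def median_center(m: SignalMatrix) -> SignalMatrix:
    """Subtract each sample column's median so column medians become 0."""
    values = m.values - m.values.median(axis=0)
    return m.advanced(values, "median_centered")


def quantile_normalize(m: SignalMatrix) -> SignalMatrix:
    """Force every sample column onto the mean-of-sorted-columns reference.

    After normalization each column's sorted values equal the across-column
    mean of sorted columns, so all empirical distributions coincide. Within
    a column rank order is preserved; tied values receive the mean of the
    reference quantiles they span.
    """
    vals = m.values.to_numpy(dtype=float)
    n, k = vals.shape
    order = np.argsort(vals, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        # average the reference over runs of ties (deterministic)
        ranks = np.empty(n, dtype=float)
        srt = order[:, j]
        col_sorted = col[srt]
        i = 0
        while i < n:
            jj = i
            while jj + 1 < n and col_sorted[jj + 1] == col_sorted[i]:
                jj += 1
            ranks[srt[i : jj + 1]] = reference[i : jj + 1].mean()
            i = jj + 1
        out[:, j] = ranks
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advanced(values, "quantile_normalized")


def _smoothing_weights(
    dist: np.ndarray, half_window: float, kind: str
) -> np.ndarray:
    if kind == "boxcar":
        return np.ones_like(dist)
    # triangular: weight 1 at distance 0, falling linearly to 0 at the edge;
    # the centre probe (distance 0) always keeps weight 1.
    w = 1.0 - dist / half_window if half_window > 0 else np.ones_like(dist)
    return np.maximum(w, 0.0)


def linear_smooth(
    m: SignalMatrix, design: Sequence[Probe], cfg: PreprocessConfig
) -> SignalMatrix:
    """Positionally smooth each sample track along every chromosome.

    Each probe value becomes the distance-weighted average of values at
    probes whose midpoints lie within ±window/2 of its own midpoint on the
    same chromosome. A window of 0 (or one smaller than probe spacing) is
    the identity.
    """
    if [p.probe_id for p in design] != list(m.values.index):
        raise ValueError("design order does not match signal matrix rows")

    half = cfg.smoothing_window_bp / 2.0
    vals = m.values.to_numpy(dtype=float)
    out = vals.copy()

    chroms = np.array([p.chrom for p in design])
    mids = np.array([p.midpoint for p in design])

    if cfg.smoothing_window_bp > 0:
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            cm = mids[idx]
            # design is sorted by (chrom, start) so midpoints are ordered
            left = np.searchsorted(cm, cm - half, side="left")
            right = np.searchsorted(cm, cm + half, side="right")
            for ii, (lo, hi) in enumerate(zip(left, right)):
                if hi - lo <= 1:
                    continue
                sel = idx[lo:hi]
                w = _smoothing_weights(np.abs(cm[lo:hi] - cm[ii]), half, cfg.smoothing_kind)
                out[idx[ii], :] = w @ vals[sel, :] / w.sum()
        spacing = np.diff(mids[chroms == chroms[0]])
        if len(spacing) and cfg.smoothing_window_bp < np.min(spacing):
            logger.warning(
                "smoothing window %d bp is below probe spacing; smoothing is "
                "effectively the identity",
                cfg.smoothing_window_bp,
            )

    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advanced(values, "smoothed")


def preprocess(
    intensities: IntensityTable,
    design: Sequence[Probe],
    cfg: PreprocessConfig | None = None,
) -> SignalMatrix:
    """Run the full chain: log2 ratio → median-center → quantile → smooth."""
    cfg = cfg or PreprocessConfig()
    m = log2_ratio(intensities)
    m = median_center(m)
    m = quantile_normalize(m)
    return linear_smooth(m, design, cfg)
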