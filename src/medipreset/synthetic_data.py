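"""Self-contained synthetic MeDIP-chip studies with known ground truth.

Emulates the study design: six diet groups (maternal mCN/mLP × offspring
CN/LP/HP), n = 5 per group, promoter regions of 1,800 bp tiled by ~210-bp
spaced probes, per-probe log2(IP/input) ratios. Planted structure:

* promoter CpG classes (HCP/ICP/LCP) realized as actual sequence
  composition and verified with the package's own classifier;
* baseline differential methylation (mLP-* vs mCN-* groups) as an additive
  log2 effect over a contiguous probe run;
* reset semantics — for a gene reset by postnatal diet D the effect is
  removed (returned to control level) in group mLP-D.

Every planted fact is recorded in a truth table so downstream peak calling
and reset classification can be scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .array_model import (
    IntensityTable,
    PAPER_GROUPS,
    Probe,
    PromoterTable,
    SampleSheet,
    write_design,
)
from .cpg_classifier import PromoterClassParams, classify_promoter, window_stats

logger = logging.getLogger(__name__)

TSS_OFFSET = 1300  # TSS index within the oriented 1,800-bp promoter sequence


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_promoters: int = 500
    probes_per_promoter: int = 9
    probe_spacing_bp: int = 210
    probe_length_bp: int = 50
    groups: tuple[str, ...] = PAPER_GROUPS
    n_per_group: int = 5
    noise_sd: float = 0.15
    baseline_probe_sd: float = 0.3
    effect_size: float = 0.6
    frac_hyper_baseline: float = 0.05
    frac_hypo_baseline: float = 0.05
    reset_category_probs: dict = field(
        default_factory=lambda: {
            "both": 0.25, "LP_only": 0.25, "HP_only": 0.25, "none": 0.25
        }
    )
    class_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # HCP, ICP, LCP
    effect_run_probes: int = 6
    partial_reset_delta: float = 0.0
    n_chroms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_hyper_baseline + self.frac_hypo_baseline > 1:
            raise ValueError("baseline fractions sum above 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not (0 < sum(self.reset_category_probs.values()) <= 1 + 1e-9):
            raise ValueError("reset_category_probs must sum to (0, 1]")
        if self.effect_run_probes > self.probes_per_promoter:
            raise ValueError("effect run exceeds probes per promoter")
        if self.effect_run_probes < 3:
            raise ValueError("effect run must span >= 3 probes")


@dataclass
class SyntheticStudy:
    design: list[Probe]
    promoters: PromoterTable
    samples: SampleSheet
    intensities: IntensityTable
    truth: pd.DataFrame
    sequences: dict[str, str] | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(self.design, outdir / "design.tsv")
        self.promoters.df.reset_index()[
            ["promoter_id", "gene_symbol", "chrom", "tss", "strand"]
        ].to_csv(outdir / "promoters.tsv", sep="\t", index=False)
        self.samples.to_tsv(outdir / "samples.tsv")
        self.intensities.to_tsv(outdir / "intensities.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.sequences is not None:
            with open(outdir / "promoters.fa", "w") as fh:
                for pid, seq in self.sequences.items():
                    fh.write(f">{pid}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Layout and truth
# ---------------------------------------------------------------------------

def simulate_design(cfg: SimConfig) -> tuple[list[Probe], PromoterTable]:
    """Probe layout: promoters spread round-robin over chromosomes,
    regions spaced far apart so peaks never interact across promoters."""
    rows_p, rows_d = [], []
    for i in range(cfg.n_promoters):
        chrom = f"chr{1 + i % cfg.n_chroms}"
        slot = i // cfg.n_chroms
        tss = 20_000 + slot * 10_000
        pid = f"PR{i:05d}"
        rows_p.append((pid, f"GENE{i:05d}", chrom, tss, "+"))
        region_start = tss - 1300
        for k in range(cfg.probes_per_promoter):
            start = region_start + k * cfg.probe_spacing_bp
            rows_d.append(
                (f"{pid}_p{k}", chrom, start, start + cfg.probe_length_bp, pid)
            )
    promoters = PromoterTable.from_frame(
        pd.DataFrame(
            rows_p, columns=["promoter_id", "gene_symbol", "chrom", "tss", "strand"]
        )
    )
    ddf = pd.DataFrame(
        rows_d, columns=["probe_id", "chrom", "start", "end", "promoter_id"]
    ).sort_values(["chrom", "start"], kind="mergesort")
    probes = [
        Probe(r.probe_id, r.chrom, int(r.start), int(r.end), r.promoter_id)
        for r in ddf.itertuples(index=False)
    ]
    return probes, promoters


def plant_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per promoter: planted class, baseline direction, reset category
    and the affected probe run."""
    classes = rng.choice(
        ["HCP", "ICP", "LCP"], size=cfg.n_promoters, p=list(cfg.class_mix)
    )
    u = rng.random(cfg.n_promoters)
    directions = np.where(
        u < cfg.frac_hyper_baseline,
        "hyper",
        np.where(u < cfg.frac_hyper_baseline + cfg.frac_hypo_baseline, "hypo", "none"),
    )
    cats = list(cfg.reset_category_probs)
    probs = np.array([cfg.reset_category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    rows = []
    for i in range(cfg.n_promoters):
        pid = f"PR{i:05d}"
        direction = directions[i]
        if direction == "none":
            reset_by, span_start = "none", -1
        else:
            reset_by = str(rng.choice(cats, p=probs))
            span_start = int(
                rng.integers(0, cfg.probes_per_promoter - cfg.effect_run_probes + 1)
            )
        rows.append(
            (pid, f"GENE{i:05d}", str(classes[i]), direction,
             cfg.effect_size if direction == "hyper"
             else -cfg.effect_size if direction == "hypo" else 0.0,
             reset_by, span_start,
             cfg.effect_run_probes if direction != "none" else 0)
        )
    return pd.DataFrame(
        rows,
        columns=["promoter_id", "gene_symbol", "cpg_class", "baseline_direction",
                 "effect", "reset_by", "span_start_probe", "span_n_probes"],
    )


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_AT_PAIRS = ("AA", "AT", "TA", "TT")


def _random_cg_free(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    """Random sequence with no CpG dinucleotide (G never follows C)."""
    bases = "ACGT"
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_no_g = np.array([p[0], p[1], 0.0, p[3]])
    p_no_g = p_no_g / p_no_g.sum()
    out = []
    prev = ""
    for _ in range(length):
        probs = p_no_g if prev == "C" else p
        b = bases[int(rng.choice(4, p=probs))]
        out.append(b)
        prev = b
    return "".join(out)


def _icp_sequence(rng: np.random.Generator, length: int) -> str:
    """Moderate-CpG sequence: GC fraction ~0.5, CpG O/E ~0.51.

    Built from dinucleotide units — 'CG' (the planted CpGs), C-carriers
    'CA'/'CT', G-carriers 'AG'/'TG', and A/T filler. No unit ends in C and
    no unit starts with G, so no CpG forms across a junction and the
    planted CpG count is exact: per 250-unit (500 bp) window the expected
    composition is 16 CpGs and 125 C / 125 G, giving O/E = 16·500/125² ≈
    0.51 with GC = 0.50."""
    n_units = length // 2
    n_cg = round(n_units * 16 / 250)
    n_c = round(n_units * 109 / 250)
    n_g = n_c
    n_at = n_units - n_cg - n_c - n_g
    units = (
        ["CG"] * n_cg
        + [("CA", "CT")[int(rng.integers(2))] for _ in range(n_c)]
        + [("AG", "TG")[int(rng.integers(2))] for _ in range(n_g)]
        + [_AT_PAIRS[int(rng.integers(4))] for _ in range(max(n_at, 0))]
    )
    rng.shuffle(units)
    seq = "".join(units)
    return seq[:length]


def _hcp_block(rng: np.random.Generator) -> str:
    """500-bp CpG island: 100 CG + 55 GC + 95 A/T units, shuffled.

    GC fraction is exactly 0.62 and the CpG O/E is at least
    100·500/155² ≈ 2.08 (junction CpGs can only raise it)."""
    units = (
        ["CG"] * 100
        + ["GC"] * 55
        + [_AT_PAIRS[int(rng.integers(4))] for _ in range(95)]
    )
    rng.shuffle(units)
    return "".join(units)


def _make_sequence(
    cls: str, rng: np.random.Generator, params: PromoterClassParams
) -> str:
    length = 1800
    if cls == "HCP":
        # CpG-dense 500-bp block fully inside the scanned −700..+200 span
        flank_a = _random_cg_free(rng, 700)
        flank_b = _random_cg_free(rng, length - 700 - 500)
        return flank_a + _hcp_block(rng) + flank_b
    if cls == "LCP":
        return _random_cg_free(rng, length)
    # ICP: moderate CpG density, GC kept below the HCP threshold
    return _icp_sequence(rng, length)


def _verify_class(seq: str, cls: str, params: PromoterClassParams) -> bool:
    if classify_promoter(seq, TSS_OFFSET, params) != cls:
        return False
    if cls == "HCP":
        st = window_stats(seq, 700, params.window_bp)
        return st.gc_fraction >= 0.6 and st.cpg_oe >= 0.8
    if cls == "LCP":
        scan_start = TSS_OFFSET + params.scan_start_rel_tss
        last = TSS_OFFSET + params.scan_end_rel_tss - params.window_bp
        return all(
            window_stats(seq, s, params.window_bp).cpg_oe < 0.3
            for s in range(scan_start, last + 1, 50)
        )
    # ICP: some window with 0.4 <= O/E < 0.6 and GC < 0.55
    scan_start = TSS_OFFSET + params.scan_start_rel_tss
    last = TSS_OFFSET + params.scan_end_rel_tss - params.window_bp
    return any(
        0.4 <= st.cpg_oe < 0.6 and st.gc_fraction < 0.55
        for st in (
            window_stats(seq, s, params.window_bp)
            for s in range(scan_start, last + 1, 25)
        )
    )


def simulate_sequences(
    cfg: SimConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    params: PromoterClassParams | None = None,
    max_attempts: int = 100,
) -> dict[str, str]:
    """Promoter-region sequences realizing the planted CpG classes.

    Each sequence is verified with the package classifier before emission
    and resampled on failure (up to ``max_attempts``)."""
    params = params or PromoterClassParams()
    sequences: dict[str, str] = {}
    for _, row in truth.iterrows():
        cls = row["cpg_class"]
        for attempt in range(max_attempts):
            seq = _make_sequence(cls, rng, params)
            if _verify_class(seq, cls, params):
                break
        else:
            raise RuntimeError(
                f"could not realize class {cls} for {row['promoter_id']} in "
                f"{max_attempts} attempts (config infeasible)"
            )
        sequences[row["promoter_id"]] = seq
    return sequences


# ---------------------------------------------------------------------------
# Intensities
# ---------------------------------------------------------------------------

def _effect_groups(reset_by: str, partial_delta: float) -> dict[str, float]:
    """Multiplier of the planted effect per diet group.

    Baseline effect is present in every maternal-low-protein group; for a
    gene reset by diet D the effect collapses to ``partial_delta`` (0 = a
    complete return to control) in group mLP-D."""
    mult = {g: 0.0 for g in PAPER_GROUPS}
    mult["mLP-CN"] = 1.0
    mult["mLP-LP"] = partial_delta if reset_by in ("both", "LP_only") else 1.0
    mult["mLP-HP"] = partial_delta if reset_by in ("both", "HP_only") else 1.0
    return mult


def simulate_intensities(
    cfg: SimConfig,
    design: list[Probe],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> IntensityTable:
    """Two-channel intensities whose log2(IP/input) carries the planted
    structure: probe baseline + group effect + Gaussian noise."""
    sample_ids, sample_groups = [], []
    for g in cfg.groups:
        for r in range(1, cfg.n_per_group + 1):
            sample_ids.append(f"{g}_r{r}")
            sample_groups.append(g)

    probe_ids = [p.probe_id for p in design]
    n_probes, n_samples = len(probe_ids), len(sample_ids)
    baseline = rng.normal(0.0, cfg.baseline_probe_sd, size=n_probes)
    signal = np.tile(baseline[:, None], (1, n_samples))

    probe_row = {pid: i for i, pid in enumerate(probe_ids)}
    truth_idx = truth.set_index("promoter_id")
    for pid_prom, row in truth_idx.iterrows():
        if row["baseline_direction"] == "none":
            continue
        mult = _effect_groups(
            row["reset_by"],
            cfg.partial_reset_delta / cfg.effect_size if cfg.effect_size else 0.0,
        )
        k0 = int(row["span_start_probe"])
        affected = [
            probe_row[f"{pid_prom}_p{k}"]
            for k in range(k0, k0 + int(row["span_n_probes"]))
        ]
        for j, g in enumerate(sample_groups):
            if mult[g]:
                signal[affected, j] += row["effect"] * mult[g]

    signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    ip = pd.DataFrame(
        1000.0 * np.exp2(signal), index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    inp = pd.DataFrame(
        1000.0, index=ip.index, columns=sample_ids, dtype=float
    )
    return IntensityTable(ip, inp)


def make_samples(cfg: SimConfig) -> SampleSheet:
    rows = [
        (f"{g}_r{r}", g, r)
        for g in cfg.groups
        for r in range(1, cfg.n_per_group + 1)
    ]
    return SampleSheet.from_frame(
        pd.DataFrame(rows, columns=["sample_id", "group", "replicate"])
    )


def simulate_study(cfg: SimConfig, with_sequences: bool = False) -> SyntheticStudy:
    """Full deterministic synthetic study for a given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    design, promoters = simulate_design(cfg)
    truth = plant_truth(cfg, rng)
    sequences = (
        simulate_sequences(cfg, truth, rng) if with_sequences else None
    )
    intensities = simulate_intensities(cfg, design, truth, rng)
    samples = make_samples(cfg)
    # the truth table also fixes the planted promoter classes
    promoters = promoters.with_classes(
        truth.set_index("promoter_id")["cpg_class"]
    )
    return SyntheticStudy(design, promoters, samples, intensities, truth, sequences)
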