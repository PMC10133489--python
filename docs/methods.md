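# Methods

## Study design and data model

The pipeline targets promoter tiling arrays assayed by MeDIP-chip: for
each sample, methylated DNA fragments are immunoprecipitated (IP channel)
and hybridized together with total input DNA (input channel) against
probes tiled over promoter regions. The modeled design has six diet
groups — maternal control or low-protein diet (mCN/mLP) crossed with
offspring control, low- or high-protein diet (CN/LP/HP) — with five
biological replicates each. Promoter regions span −1,300 bp to +500 bp
of the TSS (1,800 bp), tiled by ~210-bp-spaced probes.

All internal coordinates are 0-based half-open. The printed 1-based TSS
column is converted at the boundary: on the + strand a promoter region is
`[tss−1300, tss+500)`, on the − strand `[tss−500, tss+1300)`; both are
exactly 1,800 bp, and strand-dependent offsets are always interpreted in
transcription orientation (probes themselves are strandless). Missing or
non-positive intensities and probes not present in the design are load
errors, never imputed: the arrays modeled here have no described
imputation step, and silent hole-filling would bias the rank-based
statistics downstream.

## Normalization

Per sample, the probe statistic is `log2(IP/input)`. The chain is:

1. **Median centering** — subtract each sample column's median, removing
   global channel-intensity offsets.
2. **Quantile normalization** — all samples jointly, against the mean of
   sorted columns, so every sample shares one empirical distribution and
   group comparisons are on a common scale. Ties receive the mean of the
   reference quantiles they span (deterministic).
3. **Linear smoothing** — positional weighted average over probes within
   ±window/2 of each probe's midpoint on the same chromosome. Default
   window 600 bp (≈3 probes at 210 bp spacing) with triangular weights;
   boxcar is available. Window 0 is the identity.

The stages are tagged and must advance monotonically
(`raw_log2 → median_centered → quantile_normalized → smoothed`), so a
matrix's provenance is always explicit.

### Which stage feeds DMR calling

Differential (two-group) peak calling uses the **quantile-normalized,
unsmoothed** stage. Averaging five replicates per group already shrinks
probe noise by √5, while smoothing makes neighbouring probes share noise;
the windowed KS test treats window probes as exchangeable draws, so that
induced serial correlation inflates collective excursions and roughly
quadruples the null peak rate in our simulations. The smoothed track is
still produced and written — it is the right view for per-sample
enrichment profiles and plots.

## Peak and DMR calling

For a probe *p* the window is every probe within ±750 bp (1,500-bp
window) of its midpoint on the same chromosome; the rest is all other
probes on the array (optionally the whole array including the window —
numerically indistinguishable at array scale). The one-sided
Kolmogorov–Smirnov statistic

D⁺ = sup_x [ F̂_rest(x) − F̂_window(x) ] (clamped at ≥ 0)

asks whether window values are drawn from a *more positive* distribution
than the rest, and is converted to a p-score

−log10 p, p = exp(−2 D⁺² m n / (m + n)),

the standard asymptotic one-sided bound (m = window size, n = rest
size). An exact small-sample p-value would be *smaller* at the same D⁺
(the bound is conservative; we measured a null crossing rate of ~0.005
at the nominal 0.01), and exact enumeration at array scale is
impractical — the bound is both the safer and the cheaper choice.
P-scores are capped at 300 to keep underflow finite; ECDFs use the
right-continuous convention, making tie handling deterministic. Windows
or rests with fewer than two values score 0.

Peak assembly: maximal runs of consecutive probes with p-score ≥ 2 and
run length ≥ 2 become peaks. A run never extends across a gap of more
than the merge distance (500 bp) between consecutive probes — separate
peaks that far apart would not merge, so they cannot be one peak; this
also prevents runs from bridging two distinct promoter islands (~8 kb
apart on this design). Peaks within 500 bp of each other (gap between
spans) are then merged to a fixed point. Each peak is assigned to the
promoter contributing the most member probes (lexicographically smallest
on ties) and summarized by **PeakDM** — the mean differential log2 value
over member probes (a `max` summary is available).

Group comparisons build the differential track
`mean(group A) − mean(group B)` per probe, scan it for hypermethylated
peaks, scan its negation for hypomethylated peaks, and return the union;
peaks whose PeakDM sign contradicts their scan direction (marginal runs
straddling zero) are dropped. This construction is antisymmetric: swapping
A and B exchanges hyper and hypo exactly and negates PeakDM.

## Promoter CpG classes

Windows of 500 bp are scanned (1-bp steps by default — the span is only
900 bp, so exhaustive scanning is cheap and unambiguous) across
[TSS−700, TSS+200). With GC fraction = (#C+#G)/500 and CpG O/E =
#CpG·500/(#C·#G):

- **HCP** — any window with GC ≥ 0.55 *and* O/E ≥ 0.6;
- **LCP** — no window with O/E ≥ 0.4 (the only reading of the published
  class definitions that makes the three classes a partition);
- **ICP** — neither.

O/E is defined as 0 when a window has no C or no G (an all-A/T window is
maximally CpG-poor). `N` bases count toward window length but not toward
C/G/CpG — a conservative choice that never promotes a promoter.
Sequences too short to cover the scan span are reported UNCLASSIFIED
with a warning rather than raising, so one truncated record cannot abort
a whole-array run.

## Reset-gene logic

Three comparisons are preconfigured: baseline (mLP-CN vs mCN-CN) and the
two postnatal interventions (mLP-LP vs mLP-CN, mLP-HP vs mLP-CN). For
each gene with a baseline DMR, a postnatal comparison *resets* it iff
that comparison carries a DMR at the same promoter with PeakDM of
opposite sign — direction reversal, not mere attenuation (every
internally consistent row of the published reset table shows a sign
flip). Categories: both / LP_only / HP_only / none. A promoter with
several peaks in one comparison is represented by the peak of maximal
|PeakDM|; conflicting baseline directions at one promoter flag the gene
ambiguous and exclude it from the categories. Genes with same-direction
postnatal DMRs fall in `none` (persistent/worsened — tabulated, not
counted as reset).

The **completeness check** asks, for every reset gene and each resetting
diet D, whether mLP-D vs mCN-CN still shows a DMR at that promoter:
`complete` means none does, i.e. methylation truly returned to the
control level. It is reported as a flag, not used as a gate on the reset
category, since the class definitions stand on the sign rule alone.

The packaged per-gene PeakDM table (34 genes) contains two rows printed
with a positive baseline value and no sign reversal despite appearing
under hypomethylated resets; they are stored as printed and flagged
`anomalous`, and consistency checks cover the remaining 32 rows.

## Enrichment

Over-representation of a gene list against GMT sets uses the one-tailed
hypergeometric upper tail P(X ≥ k) with the array's gene universe as
default background (promoter-array queries must be judged against
assayable genes). Enrichment Score = −log10 p; `significant` means raw
p < 0.05, matching the study's convention; a Benjamini–Hochberg column
is emitted for context only. Gene-set annotations are always
user-supplied files — nothing is downloaded.

## Synthetic studies

The generator emits a full study — design, promoter table, sample sheet,
two-channel intensities, optional promoter FASTA — plus a truth table,
under a single integer seed (bit-identical outputs per seed).

Defaults mirror the modeled study: six groups × 5 replicates, 500
promoters × 9 probes at 210-bp spacing, probe baseline ~ N(0, 0.3)
shared across samples, probe noise σ = 0.15 log2 units, planted effect
±0.6 log2 over a contiguous 6-probe run, 5% hyper + 5% hypo baseline
promoters, reset categories uniform over {both, LP_only, HP_only, none}.
Effects are additive on the log2 scale and uniform over the run —
matching how PeakDM summarizes peaks and the simplest signal the KS
caller should detect. Reset semantics: the baseline effect is present in
all maternal-low-protein groups and removed (returned exactly to control)
in mLP-D for a gene reset by diet D; `partial_reset_delta` leaves a
residual instead, for exercising the completeness check. The mCN-LP and
mCN-HP groups are generated as nulls to keep the sample sheet faithful
to the six-group design. Intensities are emitted as input = 1000 and
IP = 1000·2^(signal), so the log2 ratio reconstructs the planted signal
exactly.

Sequence composition is constructive: HCP promoters carry a 500-bp block
of fixed unit counts (100 CG + 55 GC + 95 A/T dinucleotides, GC = 0.62,
O/E ≥ 2) inside the scan span within CpG-free flanks; LCP promoters are
CpG-free throughout (O/E = 0 everywhere); ICP promoters use a unit
alphabet in which no unit ends in C or starts with G, making the planted
CpG count exact and the expected window profile GC ≈ 0.50, O/E ≈ 0.51.
Every sequence is verified with the package's own classifier before
emission and resampled on failure (≤100 attempts).

What the generator does **not** emulate: dye bias, spatial artifacts,
fragment-level MeDIP enrichment kinetics, copy-number variation,
inter-replicate biological variance beyond iid probe noise, or realistic
genomic CpG landscapes. Passing recovery tests therefore demonstrate the
statistical machinery under the stated noise model, not robustness to
real-array artifacts.

## Operating characteristics and limitations

On default synthetic studies (10 seeds), the baseline comparison recovers
planted DMRs with mean recall 0.996 and mean precision 0.871, and
recovers planted reset categories with mean accuracy 0.996 (these numbers
are computed by the acceptance suite). The precision ceiling is a
property of the published cutoff, not of the implementation: with
p-score ≥ 2 and ≥2 probes, the per-window null crossing rate is ~0.005,
neighbouring windows share probes so each excursion forms a qualifying
run, and two one-sided scans per comparison yield roughly seven false
peaks per 4,500 probes against 50 planted DMRs. Raising the cutoff or
requiring a minimum |PeakDM| would trade recall for precision; both are
exposed in configuration, and the defaults stay at the published values.

Simulation sizes in the test suite (40–500 promoters, 6–10 seeds) are the
package's chosen validation scale: large enough that recovery statistics
stabilize, small enough that the full suite runs in well under a minute
per module.

Out of scope by design: per-sample absolute-methylation calibration,
copy-number correction, FDR control across probes (the modeled pipeline
uses a fixed score cutoff), and GO/KEGG database curation (annotation is
always a user-supplied GMT).
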