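# Methods

This note records the models implemented by `enhancerscope`, the
defaults and why they were chosen, what the synthetic locus does and
does not emulate, and the numerical conventions that matter when
reading its output.

## Coordinate conventions

All coordinates are 0-based half-open (`[start, end)`), the native BED
convention, everywhere in memory and on disk. Overlap between two
intervals requires at least one shared base (`max(starts) <
min(ends)`); abutting intervals do not overlap. No minimum-overlap
fraction is applied anywhere — a single shared base attaches a TF peak
to a DHS — because any fraction rule would be an extra free parameter;
the rule is configurable at the call sites that use it.

In-silico digestion places the cut at the first base of each
recognition-site occurrence (GATC for DpnII, GTAC for Csp6I). This
ignores the enzyme's overhang chemistry; only fragment boundaries
matter downstream, not sticky ends.

## Reporter-assay activity

Activity per candidate is `FC = FPKM_screen / FPKM_input` with FPKM
computed against each replicate's own library size. Replicates are
merged by the arithmetic mean of FCs (pooling counts first is a
reasonable alternative; the mean was chosen because it weights
replicates equally regardless of depth). Classification thresholds are
weak ≥ 1.5 and strong ≥ 3.0, both inclusive — the boundary values 1.5
and 3.0 are covered by tests because prose descriptions of such rules
are often ambiguous about inclusivity, and the inclusive reading of the
operative definition is used. Candidates whose input FPKM is zero have
undefined FC; they are flagged and excluded from ranking rather than
assigned infinity. Ranking is by descending FC with ties broken by
genomic position, and the top fraction (default 5%) is flagged using
`ceil(fraction × N)`.

## Hi-C topology

**Balancing.** Knight–Ruiz balancing is implemented as the inner–outer
Newton iteration with conjugate-gradient inner solves (the standard
`bnewt` scheme), returning the diagonal `x` with `diag(x)·M·diag(x)`
having unit row sums. Convergence tolerance is 1e-10 on the L2 norm of
the row-sum residual (comfortably below the 1e-8 dispersion the
downstream analysis assumes), outer-iteration cap 1000;
non-convergence raises an error carrying the iteration count and final
residual. All-zero rows are masked before balancing and propagate as
NaN through every downstream readout. Tests cross-check the result
against an independent damped symmetric Sinkhorn iteration — a
different algorithm converging to the same balanced matrix for
positive symmetric inputs.

**Insulation.** The raw insulation of bin *i* is the mean of
`M[a, b]` over `a ∈ [i−w, i−1]`, `b ∈ [i+1, i+w]` (default `w` = 10
bins = 100 kb at 10 kb resolution): a square window strictly above the
diagonal, so the diagonal never inflates the score. Bins within `w` of
either matrix edge are undefined. The reported score is
`log2(raw / mean(raw))` over defined bins; log-of-ratio-to-mean was
chosen over subtracting the mean log because it keeps the score's null
value at exactly 0 for a flat matrix.

**Boundaries.** `delta(i)` is the mean score over the `f` bins right
of *i* minus the mean over the `f` bins left (default `f` = 3).
Candidates are strict local minima of the score; a candidate is kept
when `max − min` of delta over `[i−f, i+f]` is at least the strength
threshold (default 0.7). Two numerical choices deserve note. First,
minima detection is plateau-aware with a 1e-9 relative tolerance: on a
noiseless block matrix the two window positions straddling a domain
junction tie exactly, and the convention reports the downstream bin of
the plateau. Second, even noiselessly the tie is broken only by
balancing bias, so a boundary is localized to *within one bin* of the
true junction; recovery tests and the acceptance script use a ±1-bin
match accordingly. The delta range is evaluated over `±f` bins; other
instantiations of the delta-filter exist, and both `f` and the range
are parameters so alternatives can be swapped in.

**Virtual 4C** is one row of the balanced matrix with the anchor's own
bin masked. Anchors spanning two bins are refused rather than averaged,
so the profile is always a genuine matrix row.

## 4C-seq profiles

Smoothing is a centered running mean over an odd window (default 21
fragments). Masked fragments — the viewpoint fragment and one neighbor
per side, where self-ligation and undigested artifacts dominate — are
excluded from numerator and denominator and stay missing in the
output. Edges use truncated windows by default; circular padding is
available and makes the smoother exactly mean-preserving, which the
property tests exploit.

Quantile normalization is joint across all samples: the r-th order
statistic of every sample is replaced by the mean of all samples' r-th
order statistics; tied input values receive the mean of the target
quantiles they span, which preserves within-sample rank order.

Interaction calling is a deliberately simple, testable caller, not a
port of published viewpoint-callers: per side of the viewpoint the
background is a monotone non-increasing isotonic fit of the smoothed
profile against distance, refitted once after dropping the 10% most
enriched fragments so genuine peaks do not inflate their own
background. Enrichment is profile/background; fragments above both the
configured residual quantile (default 0.95) and a floor of 2.0-fold,
in runs of at least `window // 3` = 7 fragments, become interaction
intervals. The enrichment floor is what controls the false-call rate:
smoothing makes neighboring residuals strongly autocorrelated, so a
pure quantile rule produces runs of mildly elevated fragments under
the null, while a two-fold floor on a 21-fragment smoothed profile
requires a sustained excursion that background noise essentially never
produces (calibrated at ≤5% of 100 background-only simulations, with
≥95% recovery of planted five-fold peaks). Calls are scale-invariant.
Divergence from rank-based multi-replicate callers is a known
limitation: this caller uses one profile at a time and has no
replicate-combination statistic; conserved calls across samples are
obtained by interval intersection instead.

## qPCR quantification

Relative expression uses the ΔΔCt method with amplification efficiency
fixed at 2 (an efficiency parameter is exposed but defaults to exact
doubling): per replicate, `ΔCt = Ct(target) − Ct(housekeeping)` paired
within replicate, and relative expression `2^−(ΔCt_test − mean
ΔCt_ref)`. A 2-cycle shift is therefore exactly four-fold. The t-test
(unpaired, two-tailed, pooled variance) is computed on ΔCt values, not
on folds, because ΔCt is the approximately normal scale; the reported
`sd` is the standard deviation of per-replicate folds, without delta-
method propagation through the exponential. In the degenerate
noiseless case (both groups zero-variance) the statistic is defined as
0 with p = 1 for identical groups.

Differential coverage tracks subtract mutant from wt per base after
lifting mutant coordinates back through the deletion map: positions at
or beyond the deletion shift by its width, and the deleted interval
itself is reported as missing rather than zero.

## The synthetic locus

The default locus is a 2 Mb chromosome carrying a 70 kb gene with two
alternative first exons (E1L, E1S) and 13 candidate DHSs, of which 6
are truly active — 2 strong (FC 4.5 and 3.8) and 4 weak (FC 1.8–2.6) —
so the census logic is exercisable in-package. The IkE120 analogue
(true FC 4.5, 120 kb upstream of the promoter) is the only DHS bound
by all six TF peak sets, lies between a convergent CTCF pair aligned
with the domain boundaries at bins 125 and 156 (10 kb bins; a third
boundary at bin 60 breaks up the background), and loops to the
promoter. The mutant locus deletes a 305 bp interval covering the DHS.
The deletion width is a modeling choice for the fixture, matching the
scale of a paired-gRNA enhancer knockout; no real cut coordinates are
encoded.

Generative models, all Poisson/multinomial — the standard first-order
noise model for sequencing counts:

* **Reporter screen** — input counts multinomial over fragment lengths;
  screen counts over length × true FC. Each DHS is represented by one
  500 bp cloned reporter fragment centered on it (reporter inserts are
  larger than the ~250 bp open-chromatin core), and 1 kb background
  tiles with FC 1 fill the chromosome, which keeps the genome-wide mean
  FC at ~1 so the FPKM ratio is an essentially unbiased FC estimator
  (regression slope vs truth within [0.95, 1.05] at depth 1e7). Default
  depth 1e6 reads per library, 2 replicates.
* **Hi-C** — expected contacts = 200 · (1+d)^−1 × 3 within domains ×
  4 at the planted loop, Poisson-sampled symmetrically. The 3× domain
  contrast is typical of mammalian TADs and gives essentially complete
  (±1 bin) boundary recovery at 200 bins.
* **4C** — expected counts = 40 / (1 + distance/50 kb) per fragment ×
  5-fold over ±2 kb around each true enhancer, Poisson-sampled; the
  viewpoint fragment ±1 is zeroed before analysis.
* **qPCR** — Ct = 25 − log2(expression) + N(0, 0.1), housekeeping at
  Ct 20 (anchors are arbitrary; only differences matter), 3 replicates.
  Default effect sizes encode the study's findings: common 3' exon E8
  and E4–E5 four-fold down in the deletion clone, E3–E4 and E6–E7
  two-fold, E1L more affected than E1S, eRNA strongly reduced, and the
  ~3× stimulation response of E8 abolished in the mutant.
* **Coverage tracks** — baseline 1 plus Gaussian peaks (sd 300 bp) at
  active DHSs with height ∝ FC, in 50 bp bins, small Gaussian noise;
  the mutant track is built on the deleted coordinate system.

Everything is deterministic given a seed; the pipeline driver fans a
single global seed out per stage by hashing the stage name, so stages
are independently reproducible and whole runs are byte-identical.

What the generator does **not** emulate: read-level artifacts
(mappability, GC bias, PCR duplicates), overdispersion beyond Poisson,
trans-chromosomal contacts, replicate batch effects, or sequence
realism beyond uniform base composition. Passing tests therefore
demonstrate that the *arithmetic and inference* are correct under the
stated generative models, not that the callers are robust to every
artifact of real libraries.

## Problem sizes

The bundled tests and the acceptance script run the full pipeline on
the 2 Mb / 200-bin / ~7,800-fragment locus; calibration suites use 100
seeded simulations for boundary and interaction recovery, 200 for
reporter-FC coverage, and 500 for qPCR fold recovery — sizes at which
the binomial uncertainty on a 95% pass criterion is small, while a
whole run stays fast on a single CPU.
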