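# Methods

## The model

`locosim` estimates the local sequencing coverage a target region will
receive in a long-read whole-genome sequencing (LRS) run, before the run is
performed. The model reduces an LRS experiment to two measurable
quantities — the whole-genome coverage `C` and the read-length distribution
`D_L` — and treats everything else (read placement) as uniform at random.

One Monte Carlo iteration proceeds as follows:

1. **Genome.** The reference chromosomes are concatenated onto a single
   0-based, half-open axis of length `G`. To model mixed samples, the
   concatenated genome is replicated once per *barcode*; each barcode is a
   disjoint span of the unified axis representing one genome copy. No
   sequence is materialised anywhere — the simulation is purely
   coordinate arithmetic.
2. **Targets.** Either fixed ROIs (BED intervals, identical across
   barcodes in chromosome-local coordinates) or synthetic insertions.
   Insertion counts per barcode are fixed or `Poisson(n_I)`; placement is
   uniform over the current genome, or *semi-random* over candidate sites
   chosen with probability proportional to site length (or user weights),
   uniformly within the chosen site. Each insertion of length `l` shifts
   every coordinate at or downstream of its position by `l` (candidate
   sites shift and stretch the same way), so the barcode genome grows to
   `G + n·l` exactly and insertions never overlap (an insertion point
   falling strictly inside an existing insertion is redrawn; after 1000
   failed redraws the run errors out).
3. **Reads.** Lengths are sampled i.i.d. from `D_L`: either
   `LogNormal(mu, sigma^2)` with `mu = ln(mean) − sigma²/2` so the
   *arithmetic mean* equals the user's mean read length, or the empirical
   multiset of record lengths from a FASTA/FASTQ file (uniform with
   replacement). Lengths are rounded to the nearest integer, floored at 1;
   no maximum is imposed. Each read is assigned to a barcode (uniformly or
   by user weights) and placed with its start uniform on `[0, G_b − L]`,
   i.e. wholly inside the barcode genome. Mean-parameterisation was chosen
   over median-parameterisation because the stopping rule below accounts
   yield through the mean.
4. **Masking.** A mask is a set of chromosome-local intervals with
   blocking weights in `[0, 1]`. A read overlapping masked intervals is
   rejected with probability equal to the *maximum* weight among the
   intervals it touches — a deterministic, order-independent combination
   that does not depend on how fragmented the mask is. Rejected reads are
   redrawn from scratch (new length, barcode and position).
5. **Stopping rule.** Sampling stops at the first read for which the
   accumulated yield `Σ L_i ≥ C·G`. `G` here is always the length of ONE
   pre-insertion genome copy, so `C` keeps its conventional
   ×-of-one-genome meaning, total yield is shared across barcodes, and the
   target is independent of stochastic insertion draws. With
   `consuming = true` every sampled read counts toward the yield (rejected
   reads waste capacity, as discarded reads do in a real run); with
   `consuming = false` only accepted reads count, and a guard aborts after
   10⁶ consecutive rejections (the mask blocks effectively everything).
6. **Local coverage.** For each target `T_r`, each same-barcode read `R_i`
   contributes `|R_i ∩ T_r| = max(0, min(ends) − max(starts))` on-target
   bases (OTB). A read whose overlap is below `min_overlap` (default 1) is
   not counted. Reads containing the target (`R_start ≤ T_start` and
   `T_end ≤ R_end`) are *full* overlaps; other overlapping reads are
   *partial*. With `scaling` on, OTB is additionally divided by the target
   length, giving mean local depth.

Over `M` iterations the per-target OTB estimate is the iteration mean,
reported with the sample SD (`ddof = 1`), `SE = SD/√M`, a
normal-approximation CI (`mean ± z·SE`, default 95%) and an empirical
percentile CI across iterations; `M = 1` degenerates to SD = SE = 0 with a
point CI. Per-iteration records are always emitted in full, so any other
statistic can be recomputed downstream. For ROI targets the per-iteration
OTB is summed over barcodes before summarising (the label identifies the
region, not the copy); in insertion mode labels index insertions within a
barcode, and each label is summarised over the iterations in which it
occurs.

For quick analytic checks, the expected global depth of an empirical run
is `coverage = L_mean · N_reads / G_haploid`.

## Determinism and parallelism

Iteration `j` at coverage index `ci` uses an RNG built from
`SeedSequence(entropy=seed, spawn_key=(ci, j))`. Iterations are therefore
statistically independent and bit-reproducible regardless of how they are
distributed over worker processes: `workers = 1` and `workers = 8` produce
byte-identical outputs. In insertion mode the per-iteration targets are
re-placed from the same child RNG, making each iteration a fully
independent replicate of the experiment.

## The weighted mask builder

Uniform placement ignores mappability, GC and chromatin biases. To let a
simulation inherit the bias of real data, an empirical per-base coverage
track (BEDGRAPH) is converted into a genome-spanning weighted mask:

1. tile each chromosome with `bin_size` bins (default 100 kb; the last bin
   of a chromosome may be short) and take the base-weighted mean coverage
   per bin, positions absent from the track counting as zero;
2. winsorize the bin means at the 10th/90th quantiles. Quantiles are order
   statistics (`lower`/`higher`), so the clip bounds are actual data values
   and winsorization is exactly idempotent;
3. `log10`-transform (zero bins floored at `epsilon = 10⁻⁶`; winsorization
   usually lifts zeros anyway, the floor only guarantees definedness) and
   percentile-scale with average ranks, `x = (rank − 1)/(n − 1)` ∈ [0, 1]
   (a single bin, or an all-tied vector, maps to 0.5);
4. map through the decreasing logistic `P(block) = 1/(1 + e^{k(x − m)})`
   with steepness `k = 10` and midpoint `m` (0.4–0.6 are sensible; `P = 0.5`
   at `x = m`). Low-coverage bins (small `x`) block strongly, well-covered
   bins hardly at all, and every weight lies strictly inside (0, 1).

A constant track gives every bin `x = 0.5` and weight exactly 0.5; weights
are non-increasing in bin coverage rank, and raising `m` never decreases
any weight.

Because the weight is a *bin mean*, a bin whose internal coverage is
heterogeneous (e.g. a well-covered bin containing a short unmappable gene)
receives a single compromise weight; sub-bin resolution would require a
smaller `bin_size`. Masks are expressed in reference chromosome
coordinates and are not shifted by insertion-mode insertions.

## Agreement statistics

To validate simulated against observed coverage across a panel of targets:

* **Lin's concordance correlation coefficient**,
  `CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with population (1/n)
  moments — the original formulation; the sample-moment variant differs by
  O(1/n).
* **Bland–Altman** bias and ±1.96·SD limits of agreement on cube-root
  transformed values (OTB counts are strongly right-skewed; the cube root
  symmetrises them and is defined at zero). Points beyond the limits are
  flagged as outliers.
* **Two-sided empirical p-values** of an observed value against the `M`
  simulated values, with the add-one estimator
  `p = min(1, 2·min((#≤ + 1), (#≥ + 1))/(M + 1))`, so `p > 0` always and
  the test is valid (null p-values are super-uniform); Benjamini–Hochberg
  step-up FDR adjustment across targets (via `statsmodels`).

## Synthetic data generator

`locosim.fixtures` emulates the external inputs so the whole pipeline runs
without downloads: chrom-sizes tables; non-overlapping labelled ROIs; FASTQ
files whose lengths follow a requested log-normal (default n = 1000, mean
10 kb, sigma = 0.5 — typical of current long-read runs; base content is
random and carries no information); and piecewise-constant BEDGRAPH tracks
with gamma-distributed segment values (shape 4, i.e. CV = 0.5, the order of
bin-level variability seen in real LRS coverage) plus designed
zero-coverage "mappability holes". What these fixtures do **not** emulate:
real chromosome size spectra, alignment artefacts, correlated coverage
along the genome, or read-length truncation by basecalling — so passing
tests demonstrate the correctness of the simulation arithmetic and
statistics, not that any particular real platform is well modelled.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small study
sizes chosen to give tight statistical checks: 1 Mb genomes with 10 kb
interior targets, 200 iterations (interior-depth check at 3·SE), 10⁵ draws
for binomial/χ²/Bernoulli frequency checks (3·SE or α = 0.001), 10⁶ draws
for 1%-tolerance mean recovery, and 100–150 random small instances for the
exact per-base OTB oracle. Read chunking in the engine (chunk ≈ 1.2·C·G /
mean length, capped at 2¹⁸) only affects speed, never results.

## Known limitations

* Uniform placement within a barcode genome; bias enters only through
  masks.
* Read *lengths* only — no base content, errors or quality scores.
* Reads are placed wholly inside the genome rather than clipped at the
  edges, keeping yield accounting exact; bases within one read length of a
  genome end are slightly under-covered.
* Eq-level masking granularity is the mask interval; weights apply to
  whole reads (reject/accept), not to partial overlaps.
* In insertion mode, masks and ROIs refer to reference coordinates and do
  not track insertion-induced shifts.
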