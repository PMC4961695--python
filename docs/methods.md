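# Methods

## Detection model

Each contig's time course $x = (x_1,\dots,x_n)$ at sampling times
$t_1 < \dots < t_n$ (hours) is screened in two parts:

1. **Amplitude.** $a = \mathrm{popSD}(x)/\mathrm{mean}(x)$. The *population*
   SD (ddof = 0) is used for every standard deviation in this package —
   z-normalisation, the amplitude statistic and the noise statistic — so
   that one convention holds throughout and the identities below are exact.
   Rows with non-positive mean are excluded (the ratio is undefined), as
   are constant rows (no phase information); exclusions are counted and
   logged, never silently folded into denominators.
2. **Periodicity.** Pearson correlation against a bank of cosine templates
   $\cos(2\pi(t-\phi)/P)$ with period $P = 24$ h fixed (no period
   estimation) and peak times $\phi$ on a half-open grid $[0, P)$ at 1-min
   steps — 1440 templates at the defaults. A peak at $P$ equals a peak at 0,
   hence the half-open grid. The highest-correlating template gives
   $r$ and the molecular peak time; ties (possible only for degenerate
   rows) resolve to the smallest $\phi$. Because the bank covers all
   phases, the maximum over the bank of $+r$ equals the maximum of $|r|$
   (the antiphase template at $\phi + 12$ h realises $-r$ as $+r$), so the
   one-sided rule loses nothing.

A contig passes at $a \ge 0.15$ and $r \ge 0.8$ (both inclusive, both
configurable). Detection statistics are computed on RPKM as-is, without log
transformation. The implementation is a single standardised matrix product
(contigs × times @ times × phases); results are identical whether contigs
are processed singly, in blocks, or all at once, and 20,000 contigs against
all 1440 phases complete in seconds on one CPU.

### Analytic cross-check

For evenly spaced samples spanning a whole number of periods, discrete
orthogonality of sin/cos makes every template have the same mean and norm,
so maximising correlation over continuous $\phi$ reduces to the
first-harmonic phase
$\hat\phi = (P/2\pi)\,\mathrm{atan2}(\sum\tilde x\sin\omega t,
\sum\tilde x\cos\omega t)$, $\tilde x = x - \bar x$. `closed_form_peak`
implements this and refuses designs that violate its premise. The grid
search must then agree within half a grid step; the test suite asserts this
on arbitrary smooth rows, not only cosines. Note the attainable correlation
for a phase offset $d$ from the generating curve is $\cos(2\pi d/P)$:
0.9999976 at the worst-case half-step offset, 0.9999992 on average over
uniformly off-grid phases — which is why fidelity checks bound the *mean*
best correlation.

## Normalisations

- RPKM: $x_{ij} = c_{ij}\cdot 10^9/(L_i N_j)$ with contig length $L_i$ (bp)
  and library size $N_j$ (mapped reads).
- z-normalisation per row with the population SD. For a noiseless cosine
  sampled over whole cycles, $\mathrm{popSD} = \text{half-amplitude}/\sqrt2$
  exactly, so the z-scored row is $\sqrt2\cos(2\pi(t-\phi)/P)$ — the
  unit-variance model curve used everywhere downstream.

## Synthetic data generator

Oscillator rows are
$b\,(1 + \sqrt2\,a_{\mathrm{true}}\cos(2\pi(t-\phi)/P)) + \varepsilon$,
non-oscillators are flat $b + \varepsilon$, with
$\varepsilon \sim N(0, (\mathrm{cv}\cdot b)^2)$ i.i.d. and values clamped at
zero. The $\sqrt2$ factor makes the planted $a_{\mathrm{true}}$ equal the
detection statistic $a$ in the noiseless limit, so truth and estimate live
on the same scale. Defaults, chosen once as typical of a bulk circadian
RNA-Seq experiment: 2000 contigs, 25% oscillators, phases uniform on
$[0,24)$ h, relative amplitudes uniform on $[0.1, 0.6]$, baselines
log-normal with median 10 RPKM and $\sigma = 1$ natural-log unit, noise cv
0.05. Exactly `round(n_contigs * frac_oscillating)` contigs are flagged
oscillators. Equal parameters (the seed is a parameter) give bit-identical
matrices.

The sampling design defaults to 24 samples every 2 h (t = 0…46 h).
"Two days of 2-hourly sampling" could equally mean 25 samples including
t = 48 h; 24 is the default because it covers exactly two full cycles,
making the trigonometric identities above exact, and the 25-sample variant
remains available (`default_design(n_samples=25)`).

### Square-wave light artifacts

Under LD, abrupt lights-on/lights-off steps elicit acute transcriptional
transients that a cosine cannot fit. These are modelled as exponentially
decaying bumps: each affected contig receives, at every transition $e$,
$s_i\,m\,b_i\,e^{-(t-e)/\tau}$ for $t \ge e$, with per-contig random sign
$s_i$, magnitude $m$ relative to the row-mean baseline $b_i$, and decay
$\tau$ (default 2 h). Transitions up to $5\tau$ before the first sample are
included so pre-sampling events leave their tails. The affected subset is a
parameter (default: all contigs). The exponential form is a minimal
plausible transient, not fitted to data; its role is to reproduce the
*direction* of the LL-vs-LD detection asymmetry (artifacts strictly reduce
detections at fixed cutoffs, monotonically in $m$), not any particular
count.

What the generator does **not** emulate: read-level sampling noise
(negative-binomial counts), correlated noise across time points, non-cosine
waveforms, multiple periods, or co-regulation structure among contigs.
Passing tests therefore show the pipeline's statistics behave as designed
on cosine-plus-noise data; they do not certify performance on waveform
shapes the model class excludes.

## Measurement noise

With fitted peak times $\phi_i$ and z-normalised rows $z_{ij}$, the
residual is $z_{ij} - \sqrt2\cos(2\pi(t_j-\phi_i)/P)$, and the noise at
sample time $t_j$ is $100 \times \mathrm{popSD}_i(\text{residual})$ percent.
The model amplitude is fixed at $\sqrt2$ — the unique value making a
noiseless normalised cosine an exact fit — rather than refit per contig; a
per-contig least-squares amplitude is available behind
`refit_amplitude=True` but off by default. The profile is summarised by its
range and mean ± popSD *across sample times*; aggregating across time
points is a design choice here (the spread could also be taken across
resampled contig subsets, which this package does not do). The statistic is
invariant to contig order and to exact duplication of the cohort, scales
linearly in the injected residual SD, and is monotone in the generator's
noise level.

## Condition comparison and homology filter

Set algebra on passing-contig IDs: unique-to-A, unique-to-B, shared, with
the conservation law $|U_A| + |S| = |A|$ (and symmetrically) property-tested.
Circular peak-time differences map to $[-12, 12)$ h, antipodes to $-12$.
The homology filter consumes precomputed tabular BLAST output (outfmt 6,
optionally with a `qcovs` column; otherwise coverage =
100 × alignment length / query length from a supplied length table). A
candidate is retained if *any single* BLASTn hit meets E ≤ 1e-20, identity
≥ 60% and query cover ≥ 60% (all inclusive at the boundary); candidates
without one are retried against BLASTx hits. Existence of homology, not
best-hit quality, is the criterion; HSPs are not combined.

## Numerical and design notes

- Ties in the grid search: first (smallest) peak time wins — determinism.
- Matrix I/O writes floats at full round-trip precision (`repr`), so
  read(write(m)) is exact.
- The pipeline manifest contains no timestamp; a rerun with the same
  configuration is byte-identical, which doubles as its determinism check.
- Per-stage random streams derive from one master seed via
  `numpy.random.SeedSequence` spawning (all derived seeds < 2^31).
- Problem sizes in the test-suite simulations (up to 2000 contigs for
  recovery checks, 500 for noise calibration, 20,000 for the throughput
  check) were chosen to make the measured rates stable at two digits while
  keeping the full suite in the tens of seconds.

## Known limitations

- Period is fixed; transcripts oscillating at other periods are scored
  against the 24-h bank only.
- No multiple-testing control; the $a$/$r$ cutoffs are the inherited,
  deliberately simple decision rule of the timetable method.
- The amplitude statistic assumes strictly positive mean expression and is
  sensitive to outliers at low expression (no log transform, no variance
  stabilisation).
- The noise statistic conflates technical and biological variation; it
  decomposes neither.
- The LD artifact model is qualitative; magnitudes and decay constants are
  not calibrated to measured light-response kinetics.
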