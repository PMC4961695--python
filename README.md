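# moltimetable

Cosine-bank (molecular timetable) detection of circadian oscillations in
time-course expression matrices, with a planted-truth simulator, light-regime
comparison, measurement-noise estimation and homology filtering.

## The problem

Time-course RNA-Seq of a plant sampled every 2 h over 2 days yields a
contig × time-point expression matrix per light regime — constant light
(LL, free-running) and a 12 h light : 12 h dark cycle (LD, entrained).
Transcripts driven by the circadian clock should oscillate with a ~24-h
period under *both* regimes: self-sustained oscillation under LL and
entrained oscillation under LD. This package implements the molecular
timetable method for finding them, for researchers analysing circadian
time-course transcriptomes (bulk RNA-Seq in crops and model plants alike).

## The method

For a contig with expression time course $x(t_1),\dots,x(t_n)$ (RPKM):

- **Amplitude** — $a = \sigma / \mu$, the population SD over the mean of the
  row: a dimensionless relative amplitude.
- **Periodicity** — the row is correlated (Pearson $r$) against a bank of
  1440 test cosine curves $\cos\!\big(2\pi (t-\phi)/24\,\mathrm{h}\big)$
  whose peak times $\phi$ tile $[0, 24)$ h at 1-min increments. The peak
  time of the best-fitting curve is the contig's **molecular peak time**.
- **Detection** — a contig oscillates if $a \ge 0.15$ and $r \ge 0.8$.
- **Condition intersection** — oscillator sets from LL and LD are
  partitioned into unique and shared contigs; the shared set is the
  circadian candidate set, optionally refined by a two-stage homology filter
  (BLASTn, then BLASTx on non-hits; E ≤ 1e-20, identity and query cover
  ≥ 60%) applied to precomputed tabular BLAST hits.
- **Measurement noise** — per sampling time, the population SD across
  oscillators of the residual between z-normalised expression and the
  unit-variance model cosine $\sqrt{2}\cos\!\big(2\pi(t-\phi)/24\big)$,
  reported in percent.

On evenly spaced designs covering whole periods, the grid search agrees with
the closed-form first-harmonic phase
$\hat\phi = \frac{P}{2\pi}\,\mathrm{atan2}\!\big(\sum \tilde x \sin\omega t,\
\sum \tilde x \cos\omega t\big)$, which the package carries as an internal
analytic cross-check.

A synthetic-data generator plants cosine oscillators of known phase and
relative amplitude among flat contigs — optionally degraded by square-wave
light-transition transients under LD — so that every stage can be validated
against ground truth. See `docs/methods.md` for model details and caveats.

## Worked example

```python
from moltimetable import MolecularTimetable, default_design
from moltimetable.synthetic import SyntheticParams, generate_timecourse

params = SyntheticParams(n_contigs=1000, frac_oscillating=0.25,
                         relative_amplitude_range=(0.2, 0.5),
                         noise_cv=0.05, seed=42)
em, truth = generate_timecourse(params, default_design("LL"))
res = MolecularTimetable(em).fit()
print(res.summary())
print(res.measurement_noise())
```

prints

```
Molecular Timetable Detection Results
=====================================================
Condition:            LL (24 h photoperiod)
Samples:              24 (t = 0..46 h)
Cosine bank:          1440 curves, period 24 h, step 1 min
Cutoffs:              a >= 0.15, r >= 0.8
-----------------------------------------------------
Contigs scored:       1000
Contigs excluded:     0
Oscillating contigs:  250
  amplitude a:        median 0.355  (range 0.184-0.513)
  best r:             median 0.992  (min 0.957)
=====================================================
measurement noise 13-16% (14 +- 1%)
```

All 250 planted oscillators (and no flat contigs) are recovered: with 5%
multiplicative noise on relative amplitudes of 0.2–0.5, the worst-case
cosine correlation is still ≈ 0.97, well above the 0.8 cutoff, while flat
contigs have $a \approx$ 0.05, well below 0.15. The 14% measurement noise is
the residual left by that 5% noise after z-normalisation.

`res.phase_profile()` tabulates (and `res.plot_profile("fig.png")` draws)
the phase-ordered expression profile: at each sampling time the passing
contigs, plotted against their molecular peak times, trace the model cosine
sweeping across the day.

The same stages are available from the shell:

```sh
moltimetable simulate --out m.tsv --n-contigs 1000 --seed 42
moltimetable detect --matrix m.tsv --out stats.tsv
moltimetable run --config pipeline.yaml   # full LL/LD pipeline + manifest
```

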