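# Methods

## Model and procedure

`circact` implements the non-parametric description of rest-activity
rhythms: no waveform is fitted; instead the statistics are ratios of
empirical variance components of the activity series itself. The
pipeline is fixed:

1. **Ingest** — parse a two-column timestamp/count file. Exactly two
   datetime layouts are accepted (`YYYY-MM-DD HH:MM:SS`,
   `YYYY/MM/DD HH:MM:SS`); anything else (e.g. day-first dates) is
   ambiguous and rejected with the offending row named. A time-only
   first column is also rejected: without dates, multi-day alignment
   across midnight would be guesswork.
2. **Resample** to one value per clock minute. Sub-minute data are
   averaged within each minute (arithmetic mean of the samples whose
   timestamps floor to that minute); minute data pass through;
   coarser-than-minute data are replicated to every minute a sample
   spans. A minute with no usable sample is a hard error — imputation
   of non-wear gaps is the user's responsibility upstream.
3. **Cutoff** (default 1): minute values *strictly below* the cutoff
   are set to 0. Strict comparison makes the default inert on integer
   count data — every positive count survives — matching the intent of
   "take all values as they are" at cutoff 1.
4. **Trim to full days** (default on): keep the first
   `floor(len/1440)·1440` minutes, anchored at the first sample.
   Midnight anchoring is available as an option
   (`trim_full_days(..., anchor="midnight")`). Skipping the trim emits
   a warning because IS and IV depend on the day/night ratio of the
   retained data.
5. **Hourly means** for IS/IV; **minute-of-day profile** for M10, L5,
   Lflex and RA.

## The statistics

With hourly values $x_i$ ($i = 1..n$, $p = 24$ per day, $d = n/p$ days),
$\bar x$ the grand mean and $\bar x_h$ the mean over days of hour $h$:

* $IS = n\sum_h(\bar x_h-\bar x)^2 \,/\, p\sum_i(x_i-\bar x)^2$ — the
  between-day-pattern share of total variance, in $[0,1]$ by the
  variance decomposition. Identical days give exactly 1; i.i.d. noise
  gives $\approx 1/d$ in expectation.
* $IV = n\sum_{i\ge 2}(x_i-x_{i-1})^2 \,/\, (n-1)\sum_i(x_i-\bar x)^2$ —
  the mean-square successive difference over the variance. For a
  noiseless 24-h sinusoid at hourly samples the closed form is
  $4\sin^2(\pi/24)\approx 0.068$; for i.i.d. noise $E[IV] = 2n/(n-1)$;
  an hourly alternation (2-h ultradian period) gives exactly 4.
* M10/L5: the minute-of-day profile (1440 cross-day means keyed by true
  clock minute) is scanned with **circular** sliding windows — all 1440
  start minutes, wrapping past midnight, which matters because L5
  typically spans midnight. M10 is the maximal 600-minute window mean,
  L5 the minimal 300-minute window mean, Lflex the minimal window of a
  user-chosen length. Ties are broken by the earliest start counting
  from 00:00 so output is deterministic.
* $RA = (M10-L5)/(M10+L5)$, scale-invariant but not shift-invariant.

IS and IV are computed on hourly values only; minute-resolution
variants are not offered, to stay comparable with published values.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sampling_rate` | `"infer"` | samples/s; inferred as the median timestamp gap, refused if >5% of gaps deviate from the median by >1 s |
| `cutoff` | 1 | zero out minute values strictly below this count threshold |
| `fullday` | true | trim to whole 1440-minute days before computing statistics |
| `flex_minutes` | off | Lflex window length, 1–1440 minutes |
| `plot` | true | write dual-day actogram + minute/hourly profile images (grand-average hourly profile in directory mode) |

## Degenerate inputs and numerical choices

* Constant signal: IS and IV are 0/0 — reported as NaN with a warning,
  never an exception, so directory runs continue. Single-day input: IS
  is identically 1 and carries no information, reported as NaN; IV is
  still reported. M10 + L5 = 0 (no activity at all) likewise makes RA
  NaN with a warning.
* Window means are computed per window with `sliding_window_view(...).mean()`
  on the wrapped profile. Mathematically tied windows can differ by
  summation-order rounding, so candidates within `1e-9` of the profile
  scale count as tied and the earliest start wins.
* Hourly blocks are consecutive 60-minute spans from the first sample.
  When a recording starts on a whole hour (all synthetic fixtures, and
  the midnight-anchor option) this coincides with clock-hour binning;
  for a mid-hour start, clock-hour binning would produce two partial
  edge blocks and break $n = 24d$, so block anchoring is preferred.
  The diurnal profile, by contrast, is always keyed by true clock
  minute-of-day, so M10/L5 start times are real clock times regardless
  of when the recording began.
* Activity values are parsed with Python's exact `float()` so that a
  written file re-reads bit-identically.
* Batch runs isolate per-file failures: a malformed file becomes a NaN
  row with a log message, not an abort.

## Synthetic generator

`circact.synthetic` renders signals with known ground truth, the basis
of the test suite: `sine` (mesor + amplitude at a 24-h period, clipped
at 0), `square` (rest-activity block wave, default 100 counts/min
08:00–20:00, 0 at night), `noise` (i.i.d. Gaussian; default mesor 10,
sd 1, chosen so clipping at 0 and the default cutoff of 1 never bite),
`ultradian` (2-h-period alternation: IV = 4 at hourly sampling) and
`composite` (pointwise sums). Records start at midnight by default so
square-wave window expectations are exact clock times, and generation
is fully reproducible from the seed.

The generator emulates the *input format and the limit behaviours*, not
physiology: no sleep inertia, napping, weekday/weekend structure, or
wear gaps. Passing tests therefore demonstrate correctness of the
statistics and the pipeline on well-formed data, not robustness to
real-world artefacts — non-wear handling is explicitly out of scope.

## Problem sizes

The test suite and the acceptance script work at the scale the method
is designed for: 7-day recordings at 1–4 samples/min for the
deterministic limits, 20–40 seeds of 7–30 day hourly noise for the
stochastic ones, and 100–1000 random profiles for the property checks.
These sizes give the stochastic means standard errors well inside the
asserted bands.

## Known limitations

* No non-wear detection/imputation, no tri-axial channel merging, no
  proprietary device formats — all deliberately out of scope.
* Coarser-than-minute input is replicated onto the minute grid rather
  than interpolated; for such data M10/L5 boundaries inherit the coarse
  resolution.
* IS on fewer than ~5 days is a noisy estimate; a week or more of
  recording is recommended.
* Plots are fixed-format PNG snapshots, not an interactive actogram.
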