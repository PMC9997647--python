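# Methods

This note documents the models and numerical choices behind `dendrobomb`,
the defaults that matter, and what the synthetic-data tests do and do not
demonstrate about real material.

## Conventions

All dates follow the Schulman (Southern Hemisphere) convention: a ring is
labelled with the calendar year *t* in which its radial growth began
(austral spring), and its growing season is taken as October *t* –
April *t*+1, the site's wet season.  A collection made in mid-year dates
the outermost complete ring to the previous calendar year.  Ring widths
are millimetres; a width of exactly 0 encodes a locally absent ring.
Tucson/RWL files are written in the classic 0.01 mm dialect with a `999`
stop marker; on read the 0.001 mm/`-9999` dialect is auto-detected from
the stop marker, which is what prevents silent 10× unit errors.

## Detrending and chronology

Each series is detrended with a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`).  Rather than fixing a closed
form for the penalty we fix the measurable contract: the smoother's
amplitude response should be 0.5 at the requested cutoff wavelength
(default 30 yr).  For unit-spaced data the spline acts as a low-pass
filter with response ≈ 1/(1 + λω⁴), giving λ = (T/2π)⁴; the response is
verified directly on sinusoid fixtures (0.51 measured at 30 yr on a 300-yr
series, ≥ 0.95 at 300 yr, ≤ 0.05 at 3 yr).  The ring-width index is the
ratio observed/fitted; the fitted curve is floored at 0.05 × the series'
median width before division so near-zero tails cannot blow up the index,
and zero widths map to index 0.

The site chronology is the year-by-year Tukey biweight robust mean of the
indices (tuning constant 9, scale = MAD, ≤ 50 iterations at 1e-8, median
fallback when the MAD is zero).  Signal statistics:

* **rbar** — mean pairwise Pearson correlation of detrended series over
  their common overlap, weighted by overlap length (≥ 10 yr);
* **EPS** = n·r̄/(1 + (n−1)·r̄), evaluated at the mean sample depth;
* **SSS(m)** = m(1 + (n−1)r̄)/(n(1 + (m−1)r̄)) per year at the per-year
  depth, so SSS(n) = 1.

The interseries correlation statistic correlates each series, detrended
and first-differenced, against the biweight mean of all the *other*
series (leave-one-out master).  This is a deliberate simplification of
COFECHA's 32-yr-spline + autoregressive prewhitening: the first difference
is the simplest high-pass that removes the common low-frequency variance,
and the statistic should be read as a relative dating diagnostic, not as a
reproduction of COFECHA output.

Segment-lag crossdating flags correlate 50-yr segments (lapped 25 yr) at
lags ±10 yr.  A segment is flagged when the best non-zero lag beats lag 0
by ≥ 0.10 **and** is significant — with the significance test
Bonferroni-corrected across the whole segments × lags search and with an
effective sample size n/1.5 (first differences of near-white series are
MA(1) with lag-1 autocorrelation ≈ −0.5, inflating var(r) by ≈ 1.5).
Without both corrections a pure-noise series is flagged almost surely;
with them the false-flag rate is at the nominal ≤ 5 % while a 5-ring
misdating against a coherent master is still detected.

## Bomb-pulse offset dating

Missing rings make dendro dates too recent by the number of missed rings
k ≥ 0.  For each candidate k the offset score is the reduced chi-square

    score(k) = (1/m) Σᵢ ((Fᵢ − C(tᵢ − k)) / sᵢ)² ,
    sᵢ² = σᵢ² + σ_curve² + σ_model² ,

where C is, by default, the growing-season average of the atmospheric
curve — the mean of the curve linearly interpolated at the seven monthly
midpoints Oct(t)…Apr(t+1).  Linear interpolation is intentional: the bomb
peak is sharp, and splines overshoot it.  A mid-February(t+1) point mode
is available for comparison with curves tabulated that way.

* **σ_model = 0.015 F14C** absorbs seasonal-allocation and curve-zone
  error: raw AMS σ (~0.002) alone would declare nearly every real ring a
  misfit, since the wood integrates a season while the curve is a zonal
  monthly average.
* **k̂ = argmin**, ties broken toward smaller k (parsimony — fewer inferred
  missing rings).  Negative k (false rings) is off by default (`k_min`).
* **Low confidence**: if the runner-up offset's total chi-square is within
  3.84 (the 95 % point of χ²₁) of the minimum, the result is flagged — the
  characteristic case is a set of samples entirely on the pre-bomb plateau
  (≈ 0.975 before 1955), where the profile is flat within noise.
* **Match verdicts** per ring use |F − C| ≤ max(3s, 0.06).  The absolute
  floor of 0.06 was calibrated against published ring/curve pairs regarded
  as agreeing, whose growing-season residuals reach ≈ 0.055; a floor of
  0.05 would call the clearest published agreement a mismatch.  Gross
  offsets (≥ a year on the steep limbs) produce residuals several times
  larger, so the floor does not blunt offset detection.

Date corrections insert the inferred rings (width 0, annotated) at
*supplied* boundary positions — locating missing rings is anatomical
evidence, outside computational scope — and shift all older rings back by
the cumulative count; the outermost ring keeps the collection-year date.
Estimating the offset again after correction must return k = 0, and the
test suite closes this loop.

### The SH zone 1-2 curve reconstruction

The package cannot ship the compiled Southern-Hemisphere zone 1-2
atmospheric record, so `synthetic_sh_zone12_curve()` provides a monthly
piecewise-linear **synthetic reconstruction**: published growing-season
averages and mid-February values of the record (ring years 1959–1976) are
used as anchor knots, joined to a 0.975 pre-bomb plateau and a smooth
post-peak decline to ≈ 0.985 by 2019.  On the bomb-peak limbs that drive
offset dating the reconstruction tracks the published record closely;
between anchors it is interpolation.  Published per-ring measurements for
the case-study trees (VTP01/VTP05/VTP07) ship alongside it in
`dendrobomb.datasets`.  Offset estimates are insensitive to the
interpolation details because the limb gradients (~0.1 F14C/yr) dwarf the
anchor residuals; users with access to the real curve file can load it
with `read_curve_csv` and use it everywhere instead.

## Climate–growth analysis

The design window holds 24 months, Jul(*t*−1)…Jun(*t*+1), labelled
relative to the previous ("prev") and current ("curr") Jul–Jun year so
that the previous growing season is Oct(prev)–Apr(prev→curr) and the
current one Oct(curr)–Apr(curr).  Seasonal aggregates take every
contiguous 1-, 2- and 3-month block ending at each window month (69
blocks); precipitation blocks are summed (accumulated totals),
temperature blocks averaged.

* **Simple correlations**: Pearson r with a stationary-bootstrap
  percentile CI (Politis–Romano geometric blocks, mean length n^(1/3) ≈ 4
  at n = 56; 1000 resamples).  "Significant" means the CI excludes zero.
  Published precedent for these defaults is thin everywhere in the field;
  they follow treeclim's conventions and are config keys, not constants.
* **Moving correlations**: 35-yr windows lagged 1 yr (a 1960–2015 span
  gives 22 windows), each with its own bootstrap CI.
* **Partial correlations**: the covariance-removal formula above, whose
  correctness is pinned by a 1e-10 agreement with the residual-regression
  oracle on random fixtures (and cross-checked against `pingouin`).  Note
  that with r_TP = 0 the partial equals r_PC/√(1−r_TC²), not r_PC — the
  two coincide only when the other climate variable is also uncorrelated
  with growth.
* **Partial-correlation significance** uses surrogate chronologies from
  circulant embedding: the sample autocovariance is embedded in a
  symmetric circulant whose FFT gives the spectral weights; complex-normal
  draws transform back to Gaussian series with the observed
  autocovariance.  Non-PSD embeddings fall back to a doubled circulant,
  then clip residual negative eigenvalues.  p = (1 + #{|r_s| ≥ |r|})/(1 +
  n_s), two-tailed, so the smallest attainable p is 1/(n_s+1).  Measured
  size against an AR(1) chronology (φ = 0.5, n = 56) is 2.5–4 % at
  α = 0.05 over 200 trials.  Simple and partial modes are labelled in all
  outputs and kept distinct.
* **No multiple-testing correction** is applied across the 24 months or 69
  seasons; outputs say so.  Gridded correlation maps are a per-cell
  map-apply of the bootstrap correlation on a long (cell, year, month)
  table; no gridded-file format dependency.

## Synthetic data

The generators encode the study conditions, not tuned test inputs:

* **Climate**: 630 mm/yr expected precipitation on a fixed monthly profile
  with ~94 % falling Oct–Apr; monthly gamma draws with relative sd 0.7 and
  zero-inflation (p = 0.4) in the five dry months, expectation preserved;
  temperature = 17.5 °C mean + 3 °C seasonal sinusoid (warmest January) +
  AR(1) monthly anomalies (φ = 0.5, innovation sd 0.8 °C).  A 500-yr run
  reproduces the annual normals within the Monte-Carlo noise.
* **Growth**: log-index gₜ = 0.3·gₜ₋₁ + β·z(climate) + tree effect +
  noise, with β = −0.4 for previous-December Tmax, +0.25 for
  previous-season precipitation, −0.3 for Aug–Sep pre-season
  precipitation; width = 1.5 mm × negative-exponential age curve ×
  exp(g), clipped to [0.01, 8] mm (the cap is a biological bound on a
  single year's increment, and keeps widths inside the Tucson field).
* **Missing rings** are confined to the sapwood (none in heartwood); a
  missed ring's width merges into its older neighbour — the physically
  faithful observation model when the terminal parenchyma between two
  layers is invisible — and the observed series is re-anchored so the
  outermost ring keeps the collection-year date.  Simple deletion is an
  option.  The default per-ring miss probability (0.1) is a free
  parameter; no quantitative rate is published.
* **Bomb curve**: logistic rise from 0.975 to a single maximum ≈ 1.63 at
  1965.5, exponential relaxation (0.06/yr) toward 1.0; monthly
  resolution.  **F14C sampling** adds Gaussian noise of sd 0.0025 (the
  span of published AMS σ is 0.0018–0.0031) to the growing-season curve
  average at the ring's *true* year, with assigned years supplied
  separately so offsets can be emulated.

What passing synthetic tests shows: the estimators recover what the
generators put in, at realistic noise levels and sample sizes.  What they
do not show: robustness to wedging/false rings, within-tree circumference
heterogeneity, climate data inhomogeneities, or curve-zone mixing in real
atmospheres — none of which the generators emulate.

## Pipeline

`run_pipeline` chains simulate → chronology → bombdate → correct →
re-chronology → re-bombdate → climcorr, with YAML configuration
(flags > config file > defaults), timestamped logging to stderr and file,
and a manifest recording the seed, all stage parameters and SHA-256
hashes of every input, so each numeric output is traceable.  Stages are
runnable standalone from the previous stage's files.  On synthetic runs
the correction stage takes its insertion positions from the simulation
truth (the stand-in for anatomical evidence); the radiocarbon stage
estimates the count blind.

Problem sizes used in the shipped checks — 56–80-yr series, 6 trees, 100-
to 200-replicate ensembles, 500–1000 surrogates/resamples — were chosen as
the smallest at which the ensemble rates quoted above are stable; all are
config keys.

## Known limitations

* The offset model assumes a *constant* offset across the measured rings
  of a radius (all misses outward of the innermost measured ring are
  shared).  Rings straddling an unnoticed internal deletion would need
  per-segment estimation; the segment-lag flags are the screening tool.
* Pre-bomb (pre-1950) material cannot be dated this way at all (flat
  plateau); the low-confidence flag reports it but nothing more.
* COFECHA's exact interseries statistic is not reproduced (see above);
  published values computed with it are comparable only in spirit.
* The biweight mean is computed per year independently; no variance
  stabilisation for changing sample depth is applied.
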