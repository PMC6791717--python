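# Methods

## Decay model and rate conventions

Median label intensity over the chase is modeled as P(t) = P(0)·e^(−kt)
with a piecewise-constant k between consecutive measurement days:
k = ln(P₀/P₁)/(t₁−t₀). A rate quoted "X % per day" means k = X/100 in
this equation. Because a division halves the per-cell label, the model
also reports divisions per day (k/ln 2) alongside k; the two differ by
the factor ln 2 ≈ 0.693 and the literature does not always distinguish
them, so both columns appear in every rate table. Negative k (an
intensity increase between days, possible in noisy series) is returned
with an explicit `negative` flag rather than raised, so QC can screen
it downstream.

Equivalent divisions between two intensities are log₂(P₀/P₁);
`divisions_to_threshold` is its ceiling with the convention that exact
equality counts as having reached the threshold (smallest n with
I·2^(−n) ≤ threshold), implemented with an integer correction loop so
exact powers of two are not a floating-point coin flip.

The percent-positive series is summarized by an ordinary least-squares
line through log₂(percent) versus day (statsmodels OLS); the half-life
is −1/slope for negative slopes and undefined otherwise. Slopes below
1e−12 in magnitude are treated as zero so a constant series does not
acquire an astronomically long, numerically meaningless half-life.

## Simulator

### Agent mode

Time advances in whole days. Each cell independently divides with its
daily probability p (its subpopulation's multiplier times the schedule
rate, capped at 1); a dividing cell of intensity I is replaced by
daughters f·I and (1−f)·I, with f = 1/2 exactly when `partition_cv = 0`
and otherwise drawn from a normal distribution centered at 1/2 with
standard deviation `partition_cv/2`, clipped to [0, 1]. Total label is
therefore conserved exactly under division, and with exact halving
every cell obeys intensity = I₀·2^(−divisions). Death, when enabled,
removes cells after division resolution. The discrete daily Bernoulli
step matches the "% per day" reporting granularity of the measurements;
no finer intracellular dynamics are modeled.

The key distributional fact used for calibration and validation is the
size-biased spine law: dividing lineages double their representation,
so a uniformly sampled cell's lineage divides with probability
2p/(1+p) per day, its division count after T days is
Binomial(T, 2p/(1+p)), and the median-intensity decay constant is
k = ln 2·2p/(1+p). Agent-mode schedules are therefore calibrated from
published k values by p = k/(2 ln 2 − k). Expected population size is
n·(1+p)^T (Galton–Watson mean growth).

### Mean-field mode

Every labeled cell's intensity is multiplied by e^(−k) per day, with no
stochastic division. Since the inference is defined on median
intensity, mean-field runs make the estimator exactly invertible; they
are the preferred source of recovery fixtures and of the end-to-end
exactness checks.

### Study conditions (defaults)

- Chase starts at day 0 (birth) with 93.6 % of cells labeled at a
  log-scale median of 1e5 AU (CV 0.5, roughly the observed histogram
  width); the induction pulse itself is not simulated.
- Rate schedule: k = 0.19, 0.09, 0.0385, 0.0175, 0.001 per day on days
  [0,7), [7,14), [14,21), [21,80), [80,600) — the published five
  interval rates. The schedule ends at day 600 and the default sample
  days are {0, 7, 14, 21, 80, 600}; chases to day 645 require an
  extended schedule.
- Subpopulations: 75 % "fast" (multiplier 1) and 25 % "slow"
  (multiplier 0.1). This two-component mix is a deliberately simple
  stand-in that produces a long-chase label-retaining plateau; it is a
  modeling placeholder, not an inferred per-cell rate distribution.
- Autofluorescence median 1e2 AU (two decades below the 1e3 AU
  detection threshold), measurement CV 0.2, 5 % contaminant
  (CD31/CD45-like) events, 200 bead events at 1e4 AU with CV 0.02,
  leak labeling 0 by default (≤ 0.05 allowed; the measured no-induction
  background is below 1 %). Death probability defaults to 0 (growth
  phase); homeostasis runs can set it equal to the division
  probability. All of these are configurable per run.
- One seeded RNG stream per run (`numpy` PCG64 from a `SeedSequence` of
  the config seed); pipeline stages derive child streams
  deterministically, and the seed is recorded in every output table.

### Measurement model

Each cell yields one event: true intensity × multiplicative log-scale
noise (CV `measurement_cv`) + an additive autofluorescence draw.
Unlabeled cells carry autofluorescence-scale intensities from the
start. Contaminant events are appended so their expected share of
tendon-role events equals `contaminant_fraction`; bead events and a
paired negative-control population (unlabeled cells through the same
measurement model, which keeps the gate calibrated to the same
background composition) are attached and flagged.

### What the generator does not emulate

Cell-cycle structure (S/G2 DNA content), compensation/spectral
overlap, doublets, instrument drift within a run, spatial arrangement
of cells, and any real heterogeneity beyond the two-component rate
mix. Passing recovery tests therefore shows the inference chain is
correct under the stated generative assumptions, not that real tendon
data satisfy them.

## Gating conventions

Bead normalization multiplies every event by
target/median(bead events), making the bead median exactly the target
and the operation idempotent; contaminant-flagged events are removed at
this step, mirroring FACS exclusion before analysis. The gate is the
99.5th percentile of the negative control by default (the placement
rule is unstated in the source protocol; 99.5 bounds false positives at
0.5 %, consistent with the sub-1 % uninduced background). Percentiles
interpolate linearly between order statistics ((n−1)·q indexing, numpy
default); medians of even counts are the mean of the central pair.
"Positive" means strictly above the gate. Whether published medians
were of all events or positives only is ambiguous, so both are emitted
(`median_all_au`, `median_positive_au`); the pipeline default fits
rates on positives (`medians_source` switches this).

## Morphometry

Counting frames are squares (default 50 µm side) placed uniformly at
random fully inside the section boundary (rejection sampling over the
bounding box; the published protocol says "at least three different
locations" without a placement rule). Membership is half-open,
[x₀,x₀+s)×[y₀,y₀+s), the standard grid convention that counts each
point once. Inner/outer classification labels a point "outer" iff its
Euclidean distance to the boundary outline (shapely distance to the
exterior ring) is ≤ the rim depth (default 20 µm); a point on the
boundary is outer. Whether density frames should avoid tendon borders
is unknown; frame placement is interior-only by construction here.

## Numerical choices and degenerate inputs

- BrdU model: fraction = −expm1(T·ln((1−p)/(1+p))) and inverse
  q = exp(log1p(−fraction)/T), p = (1−q)/(1+q) — stable at small p.
  The round trip is algebraically exact, but only while 1 − fraction is
  representable in double precision; once the window saturates
  (fraction within ~1e−13 of 1) the rate is unidentifiable, and a
  fraction of exactly 1 raises.
- Noise-free agent-mode medians are quantized to I₀·2^(−d), so the
  recovered k moves in steps of ln 2/T. Recovery checks use horizons
  with integer expected division count (T·2p/(1+p) ∈ ℤ: T = 12, 21,
  101 for p = 0.2, 0.05, 0.01), where the binomial median equals its
  mean and the quantization cancels; with measurement noise or
  partition noise the medians are continuous and no such care is
  needed.
- Empty selections (e.g. no gate-positive events) raise a dedicated
  error rather than returning 0, so "no positives" can never be read
  as "median zero". Missing controls name the absent control.
- The pipeline writes CSVs via pandas with default (shortest
  round-trip) float formatting and reads with
  `float_precision="round_trip"`, so write→read is lossless and
  manifest-equal runs are byte-identical (manifests store
  run-directory-relative paths).

## Problem sizes

The validation suite simulates 1e4–1e5 founder cells over horizons of
1–101 days (populations up to ~6×10⁵ cells), 1000 counting frames for
the density estimator and 5×10³–2×10⁴ points for the geometric
fractions; these sizes put Monte Carlo standard errors well inside the
asserted 3-SE/10 % bounds while keeping the whole suite fast.

## Known limitations

- The two-subpopulation plateau mechanism is phenomenological; the
  true per-cell rate distribution behind long-chase label retention is
  not identified by these data.
- The decay model attributes all median-intensity loss to division;
  fluorophore degradation, photobleaching-like effects or intensity
  drift would bias k upward and are not modeled.
- "% per day" conflates k with the dividing fraction per day when rates
  are large (k = ln 2·2p/(1+p) is not 100·p); both columns are reported
  but the discrepancy is inherent to the convention, not resolved here.
- Chase end is 600 days in the default schedule while some published
  summaries reference 645- or 680-day endpoints; extending the schedule
  is a one-line config change.
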