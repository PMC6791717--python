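# labelchase

Pulse-chase label-dilution kinetics: a stochastic simulator of dividing
cell populations carrying a halving heritable nuclear label, flow-
cytometry-style gating, and inference of daily proliferation rates from
the decay of median label intensity.

## The problem

In a pulse-chase division-history experiment, cells are induced to
express a stable chromatin-bound fluorophore (an H2B-GFP fusion) during
a pulse window; when induction ends, the chase begins and the label is
never replenished. Every division splits the parent's label between the
two daughters, so per-cell fluorescence halves (on average) with each
division: bright cells after a long chase are *label-retaining* cells
that divided few times, and the population's intensity decline is a
cumulative record of its proliferation. Complementary thymidine-analog
labeling (BrdU/EdU) marks cells whose lineage divided during an
administration window. This package implements the full analysis chain
for such experiments — the motivating system is postnatal mouse tendon,
followed from birth to ~2 years — and a forward simulator to validate
it.

## The model

Median label intensity is modeled by exponential (logarithmic) decay,

    P(t) = P(0) · e^(−k t),

so the decay constant between two measurement days t₀ < t₁ is

    k = ln(P(t₀)/P(t₁)) / (t₁ − t₀)   [per day],

quoted as 100·k "% per day". Because one division halves the label,
divisions per day are k/ln 2, the equivalent divisions between two
intensities are log₂(P₀/P₁), and a cell needs
⌈log₂(initial/threshold)⌉ divisions to fall below a detection
threshold. For the simulator's daily Bernoulli division process with
probability p, the lineage of a uniformly sampled cell divides with
probability 2p/(1+p) per day (the size-biased spine of the branching
process); hence k = ln 2 · 2p/(1+p), division counts after T days are
Binomial(T, 2p/(1+p)), and the expected fraction labeled by a T-day
BrdU window is 1 − ((1−p)/(1+p))^T.

## Worked example

```python
import labelchase as lc

model = lc.DilutionDecayModel.from_arrays(
    [0, 7, 14, 21, 80, 600],
    [1.0e5, 2.6448e4, 1.4086e4, 1.0758e4, 3.8309e3, 2.2776e3],
)
print(model.fit().summary())
print(lc.divisions_to_threshold(1.0e5, 1.0e3))
```

prints

```
Label-dilution decay model  P(t) = P(0) exp(-k t)
timepoints: 6   intervals: 5
   interval (days)    k (1/day)  % per day   div/day
       0-7              0.19000         19    0.2741
       7-14             0.09000          9    0.1298
      14-21             0.03850       3.85    0.0556
      21-80             0.01750       1.75    0.0252
      80-600            0.00100        0.1    0.0014
total equivalent divisions: 5.456
7
```

Reading this: tendon-like kinetics — proliferation near 19 % per day in
the first postnatal week decays to 0.1 % per day in the adult; the
median cell divides ~5.5 times over the chase; and a cell must divide 7
times (⌈log₂(10⁵/10³)⌉) before its label falls below the detection
threshold, so cells still positive after a long chase divided fewer
than 7–8 times.

The simulator and the rest of the chain run end to end from one JSON
config:

```sh
labelchase run-paper --seed 1 --out out/
labelchase infer --medians out/medians.csv --out out/rates.csv
```

which simulates the chase (agent mode by default), measures a flow
sample at each sample day (beads, negative control and contaminant
events included), bead-normalizes, gates at the 99.5th percentile of
the negative control, and fits the piecewise decay model. `labelchase
density` runs the spatial counting procedures (50×50 µm counting
frames, 20 µm inner/outer rim classification) on centroid tables.

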