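# Methods

## Model

The striatal beat-frequency (SBF) model times an interval `c` by coincidence
detection over a bank of `N_osc` oscillators whose base frequencies are
evenly spaced over a band `(f1, f2]`, `f_k = f1 + k·df` with
`df = (f2 − f1)/N_osc` for `k = 1..N_osc`. All oscillators are reset in
phase at trial onset (the neuromodulatory "start gun"); a memory block
stores the state vector at the reinforced time; a readout compares the
running state vector against the stored one at every trial time. The model
makes no claim about how the criterion is learned — the stored reference is
given — and noise enters phenomenologically as multiplicative fluctuations
of the retrieved criterion (`c̃ = c(1+x_c)`, "memory noise") and of the
oscillator frequencies (`f̃ = f(1+x_f)`).

Two oscillator substrates are implemented:

* **Cosine phase oscillators**, state `cos(2πf_k t)`. The noiseless output
  has the exact closed form of a Dirichlet kernel,
  `½·sin(πN_osc df τ)·cos(π(f1+f2+df)τ)/sin(π df τ)` per branch
  (τ = t∓c). Note the carrier frequency `f1+f2+df`: the widely quoted
  dense-bank form `f1+f2` drops an `O(df)` term and fails pointwise
  equivalence with the direct sum on small banks, so the exact coefficient
  is used throughout (including the envelope-maxima heights).
* **Morris-Lecar (ML) neurons**, the dimensionless two-variable conductance
  model with instantaneous calcium, slow potassium and leak currents.
  Default constants: `E_Ca=1.0, E_K=−0.7, E_L=−0.5, V1=−0.01, V2=0.15,
  V3=0.1, V4=0.145, g_K=2.0, g_L=0.5, ξ=1/3`. `g_Ca=1.0` gives Type 1
  excitability (oscillatory for bias currents `0.083 < I0 < 0.242`, located
  empirically by the regime scan to ±0.005); `g_Ca=0.5` gives Type 2, the
  near-sinusoidal regime used for SBF experiments, oscillatory for
  `I0 ≈ 0.14–0.30` (the printed Type 2 bounds circulating in the literature
  are internally inconsistent; the package determines them empirically).

## Morris-Lecar integration and calibration

The ML flow is integrated with a fixed-step classical 4th-order Runge-Kutta
scheme (deterministic, reproducible, empirically order-4 under step
halving), with ≈200 steps per period by default. Periods are measured from
the mean spacing of upward crossings of the post-transient trace mean
(transient: the first 20% of the trace or five periods, whichever is
longer); the coefficient of variation of cycle spacings is reported as a
quality check.

The equations are dimensionless, so Hz frequencies require a time scale
(seconds per dimensionless unit). Calibration tabulates the dimensionless
rate against bias current inside the Type 2 oscillatory interval, picks one
global time scale placing the requested band inside the attainable rate
interval (for the default band the attainable ratio comfortably covers
11.5/5.5; a per-neuron time-scale fallback exists and logs itself), and refines
per-neuron bias currents by vectorised bisection until every realised rate
is within 0.5% of its target. Because each calibrated neuron sits on a
deterministic limit cycle entered at t=0 — the reset places it at its
membrane-potential maximum — its state at any trial time is a phase
read-out of one stored period: the bank stores one 1024-sample period per
neuron and evaluates states by periodic linear interpolation, which is an
exact, memory-light substitute for storing full trial-length traces.

**ML state function.** The stored waveform is the membrane potential with
its cycle mean removed, rescaled to unit peak magnitude. Removing the mean
matters: the raw Type 2 waveform carries a negative DC component, and since reference weights sum `Nc` state samples, the
DC term (∝ `Nc`) would dominate the beat signal (∝ `√Nc`) and bury the
coincidence peak under a flat pedestal.

## Weights, normalisation and the readout

Reference weights sum the state over `Nc` retrieved criteria and divide by
the largest raw-state magnitude over the bank, keeping every signed weight
in `[−1, 1]` (a "positive" variant maps them affinely onto `[0, 1]`; both
give the same envelope behaviour). The magnitude convention coincides with
the signed maximum in the generic dense-bank case and remains well defined
when the signed maximum is non-positive or near zero. Non-positive
retrieved criteria (possible under wide uniform noise) are redrawn and the
redraw count logged.

Two readouts are provided: the dot product (used for all cosine-bank
quantitative runs, matching the closed forms) and the absolute cosine of
the angle between the weight vectors. The ML experiments always use the
angle readout: it is invariant to the running state power
`Σ_k s_k(t)²`, which for the asymmetric ML waveform fluctuates strongly
enough that the noiseless *dot* output does not even peak at the criterion.

Noise parameterisation: `level` is the relative standard deviation of `x`
for every family — normal `x ~ N(0, level²)`, uniform on
`±level·√3` — so families are comparable at equal level. Frequency noise
averages the complete output over `Nf` independently perturbed banks.

## Envelope analysis

The *envelope* of a trace is the set of local maxima of `|output|`
(plateaus resolved to their leftmost point; traces with fewer than five
interior maxima, e.g. an already-smooth envelope, are used as-is). A
four-parameter model `A·exp(−(t−μ)²/2σ²) + b` is fitted by bounded
trust-region least squares; the non-negative pedestal `b` absorbs the
incoherent coincidence floor (it fits ≈0 for cosine banks) and `σ` is
bounded below by 0.8× the noiseless envelope width — a physical floor,
since noise can only broaden the output — which prevents the fit from
locking onto a single speckle spike. The fit window is
`μ0 ± 3σ_prior` with `σ_prior = max(σ_noiseless, √2·level·c)` (see below
for the √2). Reported width is the Gaussian `σ`; the half-max width used
by the analytic half-width equation converts as `FWHM = 2σ√(2 ln 2)`.

Scalar timing is quantified by unweighted ordinary least squares of `σ` on
`c` (slope ± standard error, r²), and by superposition: traces rescaled to
relative time `t/c` and unit peak, compared by maximal pairwise RMS
distance. For speckled single-trial envelopes the superposition comparison
first applies a *fixed-width* (absolute seconds) moving average, which
suppresses speckle without being able to fabricate timescale invariance.

The analytic layer mirrors the simulation layer: the sinc-envelope width
solves `envelope(c−w/2) = envelope(c)/2` by bracketed root finding on the
first lobe (criterion-independent by construction); envelope maxima solve
`tan(N_osc x0) = N_osc tan(x0)` branch by branch between the poles of
`tan(N_osc x)`; and the mean-value half-width equation is solved for `y0`
to residual <1e−10, giving `σ = 2cθy0` — linear in `c` by construction,
with θ defaulting to the mean of `|x|` under the noise pdf
(`level·√(2/π)` normal, `level·√3/2` uniform).

## What the simulated envelope is — and is not

At the default study conditions (band 5.5–11.5 Hz, criteria 30–90 s) the
criterion-time jitter `level·c` exceeds the ≈0.1 s carrier period whenever
`level ≥ 0.01`, so the kernels of distinct retrieved criteria add with
effectively random carrier phases. The single-realisation output is then a
speckle sum: its envelope follows the *square root* of the criterion-time
density — hence Gaussian with width `√2·level·c`, which is why width grows
linearly in `c` with a slope proportional to the noise level and why a
ten-fold noise increase gives a ten-fold slope increase — but with an
irreducible ≈52% relative (Rayleigh) scatter on individual envelope
maxima. That scatter caps the per-trace Gaussian-fit r² near 0.6 and
jitters the fitted centre by a fraction of `level·c`, independent of `Nc`
and of the oscillator count. Width-regression slopes are therefore noisy
at the per-seed level even though the underlying law is clean. A smooth,
speckle-free Gaussian envelope would require either averaging envelopes
over many independent trials (not part of the model as specified) or the
coherent regime `2πf·level·c ≲ 1`, i.e. much shorter criteria or far
smaller noise.

A second structural effect: an exactly evenly spaced bank revives with
period `1/df` (100 s for 600 oscillators over 6 Hz), so the full output
contains mirror and recurrent coincidences at `t = k/df ± c̃`. The
analytic treatment keeps only the physically realisable branch, and the
noisy cosine experiments therefore evaluate the retained-branch kernel sum
(the full engine remains available via `branch="full"`). ML states admit no
branch separation, so at the highest noise level (0.1) the ML widths at
criteria whose ghost zones fall inside the fit window (45, 60, 90 s for
this bank) are systematically inflated — visible as width non-monotonicity
in the sweeps. The model can only time unambiguously for criteria and
noise spreads safely inside one revival period.

## Experiment defaults and problem sizes

Cosine experiments: 1000 oscillators, criteria {30, 60, 90} s (noiseless)
or {30, 45, 60, 75, 90} s (noisy regressions), `Nc = 500` memory samples,
noise levels 0.01/0.05 for the pdf-independence checks. ML experiments:
600 calibrated Type 2 neurons, the same criteria, normal memory noise at
levels {0.001, 0.01, 0.1}. Time grids are centred on the criterion with
step `min(1/(20 f2), c/2000)` and half-width
`max(10·lobe, 5·level·c)`. The test suite runs these sizes directly; the
acceptance script reruns the complete ML pipeline (calibration included) in
well under a minute on one core. All random draws flow from explicit seeds
through `numpy` Generators; identical configurations are bit-reproducible.

## Known limitations

* Single-trial envelope fits inherit the speckle ceiling described above;
  r² and centring accuracy of those fits measure the speckle, not the
  underlying Gaussian law.
* The bank revival time bounds the usable criterion range; widths measured
  where ghost zones overlap the fit window are biased upward.
* The ML bank stores one limit-cycle period per neuron; slow adaptation or
  drift within a trial is outside the model.
* Stochastic ion-channel gating, synaptic coupling between oscillators,
  learning of the reference weights and behavioural decision thresholds
  are out of scope.
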