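# Methods

## The model

`pawshake` implements a two-neuron half-center oscillator (HCO) model of
the cat spinal locomotor CPG.  Each neuron is a single-compartment
Hodgkin–Huxley-style cell with five intrinsic currents — fast sodium
(I_NaF, instantaneous activation m_NaF,∞³ with inactivation h_NaF),
slowly inactivating sodium (I_NaS, m·h with τ_h = 100 ms), delayed
rectifier potassium (I_K, m⁴), slowly inactivating low-voltage-activated
calcium (I_CaS, m³·h with τ_h = 485 ms) and leak — plus mutual synaptic
inhibition gated by a steep, fast (τ = 9 ms) sigmoid of the presynaptic
voltage, and an optional square pulse of excitatory conductance I_E
applied to both cells.  Units are s, mV, nS, pA and nF throughout, so
pA/nF = mV/s; the membrane capacitance is 0.001 nF.

Two bursting rhythms coexist at the canonical parameters:

* a **slow locomotor-like rhythm** (~1 Hz here: CP ≈ 0.98 s, DC ≈ 51%)
  paced by the slow calcium inactivation h_CaS, which recovers during
  each neuron's silent phase and decays during its burst; and
* a **fast paw-shake-like rhythm** (~9 Hz here: CP ≈ 0.11 s) paced by
  the slow sodium inactivation h_NaS, on which h_CaS stays almost fully
  inactivated (≈ 0.001).

The key structural ingredient for the coexistence is the very steep
h_CaS steady-state curve (midpoint −58.93 mV, slope 0.75 mV).  On the
fast rhythm the inter-burst hyperpolarizations do not reach the
deinactivation range, so h_CaS cannot recover and the fast cycle
sustains itself; on the slow rhythm the long, deep silent phases dip
below the midpoint and recharge h_CaS.  We verified numerically that a
shallower curve (same midpoint, slope ≳ 3 mV) destroys the fast
attractor entirely: the cycle-averaged h_CaS target over the fast orbit
rises above the clamp level at every level, and every fast transient
collapses.  The time constant of the calcium activation gate is the
bell-shaped rational expression τ_mCaS(V) = 0.001 / (0.02·x/(1−e^{−x/4.5})
+ 0.05·y/(1−e^{−y/4.5})) with x = V+48, y = −(V+51) (peak ≈ 3.4 ms near
−50 mV); the removable singularities at V = −48 and −51 are evaluated by
the analytic limit x/(1−e^{−x/k}) → k.

## Numerics

The right-hand side and the integrator are numba-compiled.  Integration
uses an adaptive Dormand–Prince 5(4) scheme with FSAL, absolute
tolerance 1e−8 and relative tolerance 1e−9, and cubic-Hermite dense
output on a uniform 0.1 ms grid.  A hard step cap is available
(`SolverOptions.max_step`) but off by default: the quantities of
interest are attractor and transient-episode properties, which the test
suite shows are stable to a 10× tolerance tightening (<0.5% change in
the slow cycle period) and agree with an independently run high-order
solver (scipy DOP853) to sub-millisecond spike timing over a second of
the slow rhythm.  The square pulse is handled by splitting the
integration at pulse onset and offset, so each segment has a smooth
vector field and the state at pulse offset is exact rather than
interpolated.  The whole simulator is deterministic; no seeds enter.

Degenerate inputs: non-finite states raise immediately; integration
failure raises an error carrying the last good time; a sweep cell that
fails is recorded as failed and never aborts the sweep.

## Protocol conventions

* **Phase zero** is the first spike peak of a burst of neuron #2 on the
  settled slow rhythm; a pulse at phase p starts p% of a cycle later.
* **Spikes** are local maxima of V above 0 mV separated by ≥ 1 ms.
* **Bursts** group spikes with inter-spike gaps ≤ 50 ms (fast rhythms)
  or ≤ 150 ms (slow rhythm); both lie in wide valleys of the respective
  inter-spike-interval histograms.
* **Cycle metrics**: CP is first-spike-peak to next first-spike-peak,
  BD first to last spike peak of a burst, IBI = CP − BD,
  DC = 100·BD/CP.  The identity CP = BD + IBI is exact by construction
  and asserted throughout.  DC slopes are reported in %/s.
* **Transient episodes** count post-pulse cycles with CP < 210 ms; the
  episode clock starts at pulse offset (slopes are invariant to this
  choice, intercepts are not).  The cycle count used for the 5–9
  selection is neuron #2's.  The first post-pulse burst is excluded
  from every regression (it is often degenerate).  Return to the slow
  rhythm is declared at the first completed cycle with CP ≥ 210 ms; if
  none occurs within the post-pulse horizon the episode is flagged as
  switched to the stable fast rhythm and excluded from aggregates.
* The slow attractor is settled once (consecutive cycle periods
  agreeing to 0.1%) and reused across all sweep cells; the attractor is
  unique, so re-settling per cell would only repeat work.
* The fast attractor is seeded by running the 14-variable constant-hCaS
  system at h = 0.01 for a few seconds and then releasing h_CaS as a
  dynamic variable; a cold asymmetric start relaxes into the slow basin
  because h_CaS deinactivates during the initial long silent phases.

## Desk-scale problem sizes

The package defaults mirror the full study protocol (phases 0–100% in
0.25% steps × durations 200–1200 ms in 5 ms steps; 26×26 constant-hCaS
grid at 1000 s per run).  The test suite exercises coarsened versions
chosen as representative rather than exhaustive: the 20–40% window at
1% × 20 ms (336 cells), a full-range grid at 5% × 100 ms for the
selected-fraction consistency check, ten clamp episodes spread evenly
over the selected set, and a 5×5 constant-hCaS grid at 100 s per run.
The reduced model's slowest remaining timescale is h_NaS (0.1 s), so
100 s leaves a wide margin over its settling; tail averages use the
last 20 bursts.

## Clamp (freeze) experiments

At pulse offset the integration switches to the 14-variable reduced
system with h_CaS removed from the state — not to the full system with
zeroed derivatives — so the solver's error control sees the true
dimension.  Asymmetric mode clamps each neuron at the level it reached
at offset; symmetric mode clamps both at the mean.  The number of
regressed bursts is matched to the unclamped episode's cycle count.
Baselines are means over the matched window excluding the first cycle.
The clamped system needs ~3–4 cycles to relax onto its limit cycle, and
with 5–9-cycle windows this relaxation leaves residual regression
slopes of a few 10⁻³ even though the attractor itself is trendless;
the symmetric clamp equalizes the two neurons' baselines to ~1%.

## Known reproduction limits

Several printed constants of the source model are recoverable from the
text only up to formatting ambiguity (flattened fractions).  We fixed
them by internal consistency — all voltage-dependent time constants
share the c/(…) form, and the steep h_CaS curve is forced by the
existence of the fast attractor — but a residual quantitative gap
remains: our slow rhythm carries a somewhat smaller h_CaS amplitude
(range ≈ 0.044–0.19 over a cycle), so the reference pulse leaves
h_CaS ≈ (0.026, 0.012) at offset rather than the published
(0.0311, 0.0242), and transient episodes are correspondingly shorter at
identical pulse parameters.  All qualitative structure — coexistence,
transient fast episodes returning to the slow rhythm within seconds,
the BD₂/IBI₁ vs BD₁/IBI₂ slope asymmetry and its sign pattern, the
collapse of the asymmetry under h_CaS clamping, and the linear
DC-difference law — is reproduced, and the sweep's median slopes agree
with the published ones to within ~50% with the correct strict
ordering.

## The reduced-model diagonal

Equal clamp levels make the reduced system exactly neuron-symmetric,
but the measured 20-burst-average metrics still differ slightly between
the neurons: burst durations are quantized by spike count (one
inter-spike interval ≈ 2% of BD), and at the lowest grid level
(h = 0.0075) the antiphase attractor is spontaneously symmetry-broken,
with one neuron persistently bursting ~10% longer (which neuron depends
on the initial condition; the swap invariance of the pair is exact).
Diagonal duty-cycle differences are therefore tested against the ~1
percentage-point estimator noise, not against literal zero.

## Synthetic EMG

The generator emulates the recorded paw-shake structure: episodes of
5–11 reciprocal burst cycles, initial CP 75 ms growing at 0.02 s/s by
default, flexor-like channels (IP, TA) carrying the BD trend and
extensor-like channels (MG, SO, VA, BFA) the IBI trend, antiphase
offsets of half a cycle, raised-cosine or rectangular amplitude
envelopes at 10× the noise SD over i.i.d. Gaussian baseline noise, at
3000 Hz.  Ground-truth burst tables are exact (metrics linear in burst
onset time), so regression on them recovers injected slopes to machine
precision, and the pipeline's recovery bias and test calibration are
measured against them.  Statistical tests use rectangular envelopes:
with a raised cosine the 3×SD crossing sits inside the ramp, which
compresses detected burst durations by a known, envelope-dependent
factor — a property of any threshold detector on graded envelopes, not
of the pipeline.  What the synthetic cohorts do not emulate: real EMG
spectra and motor-unit structure, amplitude nonstationarity, movement
artifacts, and co-activation synergies (VA/TA); conclusions about real
recordings therefore rest on the pipeline's construction, not on these
tests alone.

Noise floors are estimated on the raw signal over a quiet interval of
≥ 200 ms (the published procedure picks this interval by hand; we use
the minimum-variance window for reproducibility, or an explicit
interval), and the 3×SD threshold is applied to the rectified,
8-ms-smoothed envelope.  Detection debounce defaults: bursts < 10 ms
dropped, gaps < 5 ms merged; both set to zero in constructed-signal
tests.  Wilcoxon signed-rank tests are two-sided, exact for n ≤ 25.
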