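# pawshake

A multistable half-center oscillator (HCO) model of the cat spinal
locomotor CPG, with the full analysis apparatus for *transient
paw-shake-like responses*: phased conductance-pulse protocols, burst
metric extraction and regression, phase × duration sweeps, the reduced
constant-h_CaS mechanism experiments, and an EMG burst-analysis
pipeline with a synthetic EMG generator.

## The science in one paragraph

Two identical neurons coupled by mutual inhibition, each with fast
sodium, slowly inactivating sodium (τ_h = 0.1 s), delayed-rectifier
potassium, slowly inactivating low-voltage-activated calcium
(τ_h = 0.485 s) and leak currents, support **two coexisting rhythms**:
a slow locomotor-like rhythm (~1 Hz) paced by the calcium inactivation
h_CaS, and a fast paw-shake-like rhythm (~10 Hz) paced by the sodium
inactivation h_NaS.  A square pulse of excitatory conductance applied
to *both* neurons during the slow rhythm evokes a **transient fast
episode** that spontaneously returns to the slow rhythm.  Although the
model and the pulse are perfectly symmetric, the transient is not: if
the pulse lands in neuron #2's spiking phase, neuron #2's burst
duration (BD) and neuron #1's interburst interval (IBI) grow through
the episode while their counterparts stay nearly constant.  The
asymmetry is carried entirely by the small difference in h_CaS the two
neurons hold at pulse offset — clamping h_CaS there freezes the burst
metrics at asymmetric baselines with no trends, and the duty-cycle
difference between the neurons is a linear function of
h_CaS2 − h_CaS1.  Cat hindlimb EMG during evoked paw-shaking shows the
same signature: extensor IBIs and flexor BDs grow across the episode.

## Worked example

```python
from pawshake import settle_to_attractor, run_pulse_protocol
from pawshake.bursts import extract_transient_episode, regress_episode

slow = settle_to_attractor(regime="slow")
print(f"slow rhythm: {slow.frequency:.2f} Hz, DC = "
      f"{100 * slow.burst_duration / slow.cycle_period:.0f}%")

traj = run_pulse_protocol(slow, p_pul=20.0, d_pul=0.950, g_E=1.0)
off = traj.meta["offset_state"]
print(f"hCaS at pulse offset: neuron1 = {off[6]:.4f}, "
      f"neuron2 = {off[14]:.4f}")

ep = extract_transient_episode(traj)
for m in ("BD", "IBI"):
    s1 = regress_episode(ep, m, 1).slope
    s2 = regress_episode(ep, m, 2).slope
    print(f"{m} slopes: neuron1 = {s1:.4f}, neuron2 = {s2:.4f}")
```

prints

```
slow rhythm: 1.02 Hz, DC = 51%
hCaS at pulse offset: neuron1 = 0.0263, neuron2 = 0.0122
BD slopes: neuron1 = 0.0214, neuron2 = 0.0250
IBI slopes: neuron1 = 0.0149, neuron2 = 0.0071
```

i.e. the slow rhythm runs at ~1 Hz; the 950 ms pulse at 20% phase
leaves neuron #1's calcium current less inactivated than neuron #2's
(it was hyperpolarized when the pulse arrived), and over the transient
episode BD grows faster for neuron #2 while IBI grows faster for
neuron #1 — the asymmetric signature.  Slopes are dimensionless
(seconds of metric per second of episode time).

A command line mirrors the library:

```sh
pawshake simulate --regime slow --p-pul 20 --d-pul 0.95 --g-e 1
pawshake sweep --phase-range 20 40 --dur-range 0.7 1.0 --out win
pawshake reduced-grid --run-time 100 --h-step 0.0031
pawshake freeze --mode symmetric
pawshake synth-emg --n-episodes 5 --out-dir synth
pawshake emg synth/S1_Data_*.txt
```

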