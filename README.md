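# nirskinetics

Analysis pipeline for ambulatory continuous-wave near-infrared spectroscopy
(NIRS) of lower-limb hemodynamics — tibia (bone) and gastrocnemius (muscle) —
during a four-posture protocol: 5 min supine baseline, 10 min corridor
walking, 5 min quiet standing, 5 min supine recovery.  It converts raw
two-wavelength, three-distance optical recordings into hemoglobin
concentration changes and tissue saturation, aligns the two devices from
shared event markers, applies the reference filtering chain, and reduces the
signals to posture-transition kinetics and plateau statistics, together with
the cohort-level statistical battery.

Because raw recordings of this kind are rarely shared, the package includes
a **forward simulator**: it generates synthetic device exports whose
transition amplitudes, time constants, noise, cadence artifact and clock
offsets are all known, so every pipeline stage is verifiable by parameter
recovery — no real data required.

## The signal model

With attenuation `A` (OD) measured at wavelength λ and source–detector
separation ρ:

* **Modified Beer–Lambert law (MBLL)** — concentration changes at the middle
  transmitter (Tx2, 35 mm; penetration ≈ 17.5 mm, spanning the anterior
  tibial cortex and medulla):

  `ΔA(λ, ρ, t) = [ε_O2Hb(λ)·Δ[O2Hb](t) + ε_HHb(λ)·Δ[HHb](t)] · DPF · ρ`

  a 2×2 linear system per sample; `ΔtHb = ΔO2Hb + ΔHHb` always.

* **Spatially resolved spectroscopy (SRS)** — absolute saturation from the
  attenuation slope across the three separations (diffusion approximation):

  `μ_a(λ) = (1 / 3μ_s′(λ)) · (ln10 · ∂A/∂ρ − 2/ρ̄)²`,
  `μ_s′(λ) = k·(1 − h·λ)`,
  `TSI = 100 · O2Hb / (O2Hb + HHb)`.

* **Kinetics** — time to 95 % of the TSI nadir after the supine→walk
  transition (`t95 = τ·ln 20` for a mono-exponential approach); stand
  time constants for O2Hb and tHb over the first 120 s after walk→stand
  (log-curve fit `y = a + b·ln(t + t0)` *and* a mono-exponential
  cross-check `y = y∞ − A·e^(−t/τ)`, both reported); last-minute plateau
  deltas between adjacent postures.

Device constants follow the tibial/gastrocnemius probe settings
(853/762 nm, DPF 7, k 1.5, h 5·10⁻⁴; 845/759 nm, DPF 5.24, k 1.63,
h 5.5·10⁻⁴; 50 Hz), and the analysis defaults are the reference chain:
0.05 Hz zero-phase low-pass, 5 s moving average, 60 s plateau windows,
120 s fit window.

## Worked example

```python
import nirskinetics as nk
from nirskinetics.synthetic import QUIET

truth = nk.SimulationTruth(noise=QUIET)          # noiseless group-mean truth
rec_t = nk.simulate_device_recording(truth, "tibia", clock_offset=0.0)
rec_g = nk.simulate_device_recording(truth, "gastrocnemius", clock_offset=-3.84)
segs, sync = nk.process_pair(rec_t, rec_g)       # sync, convert, filter, segment

t95 = nk.time_to_95_nadir(segs["tibia"], "TSI")
tau = nk.fit_stand_tau(segs["tibia"], "tHb")["exponential"]
plat = nk.plateau_deltas(segs["tibia"])
print(t95.t95_nadir, tau.tau, plat.delta("walk", "stand", "tHb"))
```

prints (see `examples/03_transition_kinetics.py` for the full script):

```
synchronization: shift +3.84 s, max residual 0.000 s
  t95 of TSI nadir    125.6 s   (truth 125.4 s)
  stand tau tHb        37.7 s   (truth 37.5 s; log-curve method 36.5 s)
  dtHb walk->stand    +9.79 µM   (truth +9.80)
```

The tibial TSI takes ~126 s to cover 95 % of its walking desaturation
(muscle: ~55 s — slower bone kinetics), tibial total hemoglobin recovers on
standing with τ ≈ 38 s, and the walk→stand blood-volume increase is
≈ +9.8 µM.  The `examples/` directory has one narrative script per
capability: simulation/export, spectroscopy round trips, transition
kinetics, and the cohort study with statistics.

A thin CLI wraps the same functions:

```sh
nirskinetics simulate --seed 7 --out-dir exports/
nirskinetics kinetics --tibia exports/tibia.tsv --gastro exports/gastrocnemius.tsv
nirskinetics reproduce --subjects 10 --seed 0 --out-dir results/
```

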