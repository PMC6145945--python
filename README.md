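# chimotor

Single-molecule stepping analysis of the processive chitinase *Serratia
marcescens* ChiA (SmChiA) — a linear molecular motor that hydrolyses
crystalline chitin and moves along a single chitin chain without ATP,
operating as a **burnt-bridge Brownian ratchet**.

High-precision particle tracking (a 40-nm gold nanoparticle probe imaged
at 0.5 ms with ~0.3 nm localization precision) resolves the motor's
~1.1 nm forward and backward steps, the length of the reaction product
chitobiose (1.04 nm). `chimotor` re-implements the complete analysis chain
that turns such noisy trajectories into a chemo-mechanical kinetic scheme:

1. **Simulation** (`chimotor.simulate`) — a kinetic Monte Carlo generator
   of stepping trajectories: step kinds drawn with fixed probabilities
   (forward / double forward / backward, a recovery step always follows a
   backward step), exponential dwells `dt = ln(1/r)/k`, camera sampling
   and pause-wise Gaussian localization noise.
2. **Localization** (`chimotor.localize`) — symmetric 2D-Gaussian fitting
   of diffraction-limited spots; localization precision and intensity
   summaries.
3. **Trajectory preparation** (`chimotor.trajectory`) — rotation onto the
   motion axis (`on = cosθ·x + sinθ·y`, `off = −sinθ·x + cosθ·y`) and
   running-median denoising.
4. **Step detection** (`chimotor.stepfind`) — iterative chi-square plateau
   splitting with counter-fit *S*-value model selection (Kerssemakers-type
   step finder), plus significance pruning of sub-threshold steps.
5. **Statistics** (`chimotor.stepstats`, `chimotor.dwell`) — Gaussian-mixture
   step-size distributions with area ratios; step categorization (1-nm
   forward, 2-nm forward, backward, recovery); dwell-time fits:
   `y = a·exp(−b·x)` for single-step categories and the convolution
   `y = a·[exp(−b·x) − exp(−c·x)]` for the two-state pause before 1-nm
   forward steps; velocities, run lengths and processivity.
6. **Kinetic scheme** (`chimotor.scheme`, `chimotor.kinetics`) — assembly of
   the reaction cycle: fast substrate-assisted catalysis
   (τ ≈ 2.9 ms, k_cat ≈ 345 s⁻¹) competing with backward stepping
   (τ ≈ 18.3 ms, k_back ≈ 54.6 s⁻¹), product release
   (τ = 23.9 − 17.1 = 6.8 ms) and rate-limiting decrystallization + chain
   sliding (τ ≈ 17.1 ms); forward-rectification probability
   k_cat/(k_cat + k_back) ≈ 86.3 %; forward/backward-state equilibrium
   K = k_dec/k_back ≈ 1.1 (ΔG ≈ −0.04 kcal/mol at 25 °C); Michaelis–Menten
   kinetics with substrate inhibition
   `v = kcat·[S]/(Km + [S] + [S]²/Ksi)` and the kinetic isotope effect
   (kcat ratio H₂O/D₂O) that identifies the fast time constant as the
   chemistry.

Because no raw trajectory data are deposited, the simulator doubles as the
package's ground-truth engine: the pipeline's self-consistency mode
simulates trajectories at the measured parameters, re-analyses them blind,
and verifies that every time constant survives the detection chain.

## Worked example

```python
from chimotor import PipelineConfig, analyze_trajectories
from chimotor.pipeline import simulate_ensemble

cfg = PipelineConfig(seed=42, n_trajectories=10)
cfg.sim.n_events = 60
trajs = simulate_ensemble(cfg)          # kMC + camera noise
result = analyze_trajectories(trajs, cfg)  # detect, categorize, fit
print(result.mixture.summary())
print(result.scheme.summary())
```

prints

```
Step-size mixture (3 Gaussians, n=535)
  peak -0.99 nm  sd 0.14 nm  ratio  12.4 %
  peak +1.07 nm  sd 0.15 nm  ratio  73.6 %
  peak +2.17 nm  sd 0.17 nm  ratio  14.0 %
Processive reaction cycle (time constants in ms, rates in s^-1)
  substrate-assisted catalysis: tau =   2.9  (k_cat = 342)
  release+decrystallization+sliding: tau =  25.9
  decrystallization+sliding:    tau =  20.2  (k_dec = 49.5)
  product release (derived):    tau =   5.7
  backward step:                tau =  19.5  (k_back = 51.2)
  2-nm forward step:            tau =  28.8
  unit step d = 1.04 nm
  P(catalysis from state A) = 87.0 %
```

The detected step-size peaks sit at ±1.1 and +2.2 nm (the chitobiose
step and its double), the event ratios match the configured
69.3 / 14.2 / 16.5 %, and the recovered time constants land near the
generator inputs (2.9 / 23.9 / 18.3 / 17.1 / 26.0 ms) even from only ten
short trajectories; the 50-trajectory default configuration recovers all
of them to within a few percent.

The same loop is available from the shell:

```bash
chimotor all --config examples/pipeline.yaml --out run/
chimotor simulate --seed 7 --out sim/           # trajectories only
chimotor stepfind sim/trajectory_*.csv          # step tables from CSVs
chimotor mmfit kinetics.csv                     # substrate-inhibition fit
```

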