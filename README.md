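# bouncework

Mechanical work partition and spring-mass-actuator analysis of treadmill
running.

## The problem

During running, part of the mechanical work of each stride is not done by
muscles acting at joints but by deformation of soft tissues — heel pad,
viscera, muscle bulk wobbling on the skeleton. Two classical measurements
bracket that contribution:

* **Total work** `W_tot± = W_com± + W_int,R± + W_int,L± + W_int,trunk±`,
  the sum of the external work to move the centre of mass (CoM) against the
  surroundings — computed by double integration of the ground-reaction
  force (GRF): `a_f = F_y/m`, `a_v = F_z/m − g`,
  `E_com = ½m(v_f − v_belt)² + ½m v_v² + m g S_v` — and the internal work
  to move the limb and trunk segments relative to the CoM,
  `E_int,i = ½(m_i V_i'² + I_i ω_i²)`, with energy transfer allowed between
  segments of the same limb but not between limbs or with the CoM.
* **Joint work** `W_j±`, from sagittal-plane bottom-up inverse dynamics
  (ankle → knee → hip treated as hinges), with joint powers
  `P_j = M_j·ω_j` summed per limb before integration.

Their residual per stride is the **soft-tissue work**

```
W_ST± = W_tot± − W_j,R± − W_j,L±
```

The package also characterises the bouncing leg itself. During each
contact, the GRF projected on the leg axis (centre of pressure → greater
trochanter) is regressed on leg length and its rate,

```
F_projected = cst + k·L_leg + c·V_leg
```

— a linear spring of stiffness `k` with a parallel actuator of coefficient
`c` (negative = damper) — and the force–length hysteresis area `Δ_area`
(work absorbed in compression minus work returned in decompression,
`−∮F dL`) measures the deviation from ideal elastic rebound. Pearson
correlations with Fisher-z confidence intervals link `Δ_area` to the
soft-tissue work and the damping across conditions.

Because every stage is easy to get subtly wrong, the package ships a
synthetic treadmill-gait generator whose trials are Newton-consistent by
construction and carry an exact ground-truth ledger (true CoM trajectory,
joint moments, injected soft-tissue dissipation), so the whole pipeline is
testable without laboratory data.

## Worked example

```python
import bouncework as bw

params = bw.SimulationParams(n_strides=10, wobble=bw.WobbleParams())
trial, truth = bw.simulate_trial(params, seed=1)
results = bw.RunningWorkPartition(trial).fit()
print(results.summary())
```

prints

```
Running work partition
==========================================================
strides analysed     10
steps fitted         20
----------------------------------------------------------
per-stride work, J/kg (mean ± sd)      +          -
  W_com           2.492 ± 0.002    -2.491 ± 0.001
  W_tot           6.180 ± 0.022    -6.190 ± 0.022
  W_j_R           3.091 ± 0.010    -3.018 ± 0.011
  W_j_L           3.090 ± 0.012    -3.032 ± 0.012
  W_ST           -0.001 ± 0.026    -0.141 ± 0.026
----------------------------------------------------------
spring-mass-actuator fit (per step mean ± sd)
  k         -74.87 ± 0.89    N/kg/m
  c          -0.15 ± 0.01    N·s/kg/m
  RMSE       1.714 ± 0.043   N/kg
  R²         0.922 ± 0.003
  Δ_area     0.408 ± 0.010   J/kg
```

Reading the output: positive and negative total work balance (steady-state
running at constant belt speed); the wobbling-mass element injected into
this trial shows up as net negative soft-tissue work (`W_ST− ≈ −0.14 J/kg`
per stride, close to the generator's ledgered dissipation of 0.16 J/kg),
while on a rigid trial both `W_ST` columns are ≈ 0. The spring fit reports
the raw regression coefficient on `L_leg`, which is negative on real
force–length loops (force peaks when the leg is shortest); its magnitude is
the leg stiffness. `results.work` and `results.springs` expose the
per-stride and per-step tables as DataFrames;
`results.condition_summary()` applies right/left-then-stride averaging, and
`bouncework.correlation_table` computes the Pearson/Fisher report.

The same pipeline runs from the shell:

```bash
bouncework simulate --params params.yaml --seed 17 --out trial/
bouncework analyze --force trial/sim_force.tsv --markers trial/sim_markers.tsv \
                   --meta trial/sim_meta.tsv --out trial/results/
bouncework correlate --in study_dir/
```

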