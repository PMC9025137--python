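# myocolor

Models of myoglobin-driven surface browning of beef during refrigerated
storage, for food scientists and process engineers who need to predict the
color shelf-life of fresh meat under different storage temperatures and
modified-atmosphere oxygen levels.

Consumers reject beef once its bright "bloomed" red fades to brown. The red
color comes from oxymyoglobin (MbO₂) at the cut surface; browning is the
accumulation of oxidized metmyoglobin (MMb). `myocolor` implements two
complementary predictors of the normalized CIELAB redness a\*/a\*₀ and the
machinery to calibrate and test them:

**Reaction–diffusion model.** Myoglobin chemistry is a mass-action network
over the three redox forms (Mb, MbO₂, MMb) plus dissolved oxygen,

&nbsp;&nbsp;&nbsp;&nbsp;dCᵢ/dt = Σⱼ aᵢⱼ kⱼ Π_{aᵢⱼ<0} Cᵢ^(−aᵢⱼ),

with oxygen alone also diffusing inward from the exposed surface
(∂O₂/∂t = D_O₂ ∂²O₂/∂x² + reactions) on a 1-D depth grid, Dirichlet O₂ at
the surface set by the package headspace and zero flux at the tray. Every
rate constant is rescaled from its 20 °C reference value with a single
activation energy, kⱼ(T) = kⱼ(T_ref)·exp(−(Ea/R)(1/T − 1/T_ref)). Surface
color follows a threshold rule on the ratio r = MbO₂/(MMb + Mb) =
MbO₂/(1 − MbO₂): a\*/a\*₀ = 1 while r ≥ S, and r/S below.

**Gompertz phenomenological model.** a\*(t) follows a modified
(Zwietering-parameterized) Gompertz curve with lag, maximum decay rate
μmax, and initial/final plateaus; log-linear regressions express lag and
μmax as functions of the four storage factors (temperature, O₂ %, aging
days, cutting angle).

**Calibration.** The threshold S and activation energy Ea are identified by
staged least squares against observed a\*/a\*₀ kinetics: a coarse-mesh scan
over integer S candidates and an Ea grid, Levenberg–Marquardt refinement of
Ea, and a 400-node-mesh verification producing a per-condition
root-residual table.

**Synthetic data.** A generator emulates the storage experiments (13-run
definitive screening design over 4 factors at 3 levels, 15-min sampling
over 15 days, three-phase kinetics, Gaussian noise), so the entire pipeline
is testable without laboratory data. The bundled 4-reaction scheme is a
documented stand-in, tuned by `scripts/tune_default_scheme.py`; drop in
your own scheme file for quantitative work.

## Worked example

```python
import numpy as np
import myocolor as mc

scheme = mc.default_scheme()
grid = mc.SpatialGrid(depth_m=0.02, n_nodes=400)
times = np.linspace(0, 15 * 86400, 361)          # 15 days, hourly

for T in (2.0, 6.0, 10.0):
    cond = mc.StorageConditions(T_C=T, pO2_pct=20.0)
    traj = mc.simulate(scheme, grid, cond, times_s=times)
    ck = mc.predict_color(traj, mc.ColorMapParams(S=2.0))
    plateau = ck.times_h[np.flatnonzero(ck.values < 1 - 1e-6)[0]] / 24
    print(f"T = {T:4.1f} °C: red plateau lasts {plateau:.1f} d, "
          f"a*/a*0 at day 15 = {ck.values[-1]:.2f}")
```

prints

```
T =  2.0 °C: red plateau lasts 10.0 d, a*/a*0 at day 15 = 0.74
T =  6.0 °C: red plateau lasts 8.2 d, a*/a*0 at day 15 = 0.62
T = 10.0 °C: red plateau lasts 6.7 d, a*/a*0 at day 15 = 0.51
```

i.e. at 2 °C under 20 % O₂ the surface stays fully red for ~10 days and
then browns, and each 4 °C of extra warmth costs roughly two days of
plateau. Calibration is one call:

```python
design = mc.make_design("custom", runs=[
    mc.StorageConditions(T_C=T, pO2_pct=o2)
    for T in (2., 6., 10.) for o2 in (20., 100.)])
data = mc.synth_from_rd(scheme, design, S=2.0, Ea_kJ_mol=32.5,
                        noise=mc.NoiseModel(sigma=0.0), dt_min=60)
result = mc.calibrate_rd(scheme, grids=(100, 400), dataset=data)
print(result.S, result.Ea_kJ_mol)    # -> 2.0 32.5
```

A `myocolor` console script exposes the same pipeline
(`myocolor simulate / predict-color / phenom-fit / calibrate / synth /
report`; see `--help`).

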