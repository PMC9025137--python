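# Methods

This note documents the models implemented in `myocolor`, their
assumptions, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Reaction–diffusion model

The meat cut is a 1-D single-compartment slab (default depth 0.02 m —
ribeye steaks are typically 2–3 cm thick — configurable). The state is the
concentration of every scheme species at every depth node: the three
myoglobin redox forms as dimensionless fractions summing to 1, and
dissolved O₂ in mol·m⁻³. Chemistry is exact mass-action kinetics; the
reaction order of each reactant is the magnitude of its negative
stoichiometric coefficient. Oxygen is the only transported species: it
diffuses from the exposed surface with constant diffusivity D_O₂ (default
1×10⁻⁹ m²·s⁻¹, the order of O₂ diffusion in aqueous tissue; no temperature
or pressure dependence is modeled). Neglected on purpose: the ferryl
(MbFe⁴⁺) form, enzymatic/mitochondrial MMb reduction pathways, fat
compartments, 2-D transfer, and microbial effects.

**Temperature.** All rate constants share one activation energy and scale
as k(T) = k(T_ref)·exp(−(Ea/R)(1/T − 1/T_ref)) with T_ref = 293.15 K. The
non-relative form exp(−Ea/RT) sometimes written for this correction does
not return the reference constants at the reference temperature, so the
relative form is used throughout; fitted Ea values are only meaningful
under this convention.

**Boundaries and initial state.** Surface O₂ is Dirichlet at
α·(headspace O₂ %), with α = 0.0135 mol·m⁻³·%⁻¹ a Henry-type solubility
coefficient stored in the scheme file (0.27 mol·m⁻³ under air-like 20 %
O₂, the order of dissolved-O₂ saturation in chilled aqueous media). The
bottom boundary is zero-flux (tray contact). The default initial profile
is a just-bloomed surface — fractions (Mb, MbO₂, MMb) = (0.05, 0.90, 0.05)
at x = 0 blending linearly over a 2 mm bloom depth into the anoxic deep
composition (0.95, 0, 0.05) — with O₂ zero except at the pinned surface
node. When D_O₂ = 0 there is no diffusion operator and no boundary is
imposed; the system is then node-wise well-mixed chemistry, which is what
the 0-D oracle tests exploit.

**Numerics.** Method of lines with second-order central differences on a
uniform grid (mirror node for the zero-flux boundary), integrated with
LSODA and a banded Jacobian (node-major state ordering gives half-bandwidth
equal to the species count). Defaults rtol 1e-6, atol 1e-9; rate constants
span four orders of magnitude, so a stiff implicit method is required.
Conservation of total myoglobin is a linear invariant of the right-hand
side and is preserved by the multistep integrator to roundoff. Outputs are
clipped to non-negative values; anything below −1e-9 aborts the run.
Because the surface O₂ node is pinned, the surface myoglobin chemistry is
autonomous and the predicted *surface* color series is essentially
mesh-independent for the bundled scheme; mesh refinement matters for
sub-surface profiles (and would matter for surface color under a
flux-limited boundary). Mesh-convergence comparisons therefore allow a
1e-9 solver-noise floor.

## Color map

With the three forms summing to one, r = MbO₂/(MMb + Mb) = MbO₂/(1 − MbO₂).
The default map is the continuous normalized threshold rule
a*/a*₀ = min(r/S, 1): fully red while the surface ratio is above S,
proportional below, continuous at r = S. A literal discontinuous variant
(a*/a*₀ = r below S) is kept behind a compatibility flag, and an opt-in
logistic threshold (width w in ratio units) is provided because a sharp
single threshold is an idealization — real consumer-perceived color change
is better described by a window of thresholds. Note the two ratio
conventions MbO₂/(MMb+Mb) and MbO₂/MMb differ by exactly a factor
1 + Mb/MMb; they agree within 5 % only once Mb/MMb ≤ 0.05, which holds
late in storage when MMb has accumulated.

## Gompertz phenomenological model

a*(t) = a0 + (af − a0)·exp(−exp(μmax·e·(lag − t)/((af − a0)·c) + 1)),
the Zwietering parameterization with an extra configurable factor c on the
denominator (default c = ln 10, mirroring the log₁₀ convention of
predictive microbiology; with c = 1 the inflection tangent has slope
exactly μmax, in general μmax/c — fitted μmax values are comparable only
under a fixed c). Curve fitting is bounded trust-region least squares
(lag ∈ [0, t_max], μmax ≤ 0) with data-driven initial guesses; flat series
are fitted but flagged degenerate.

The factor regressions are ordinary least squares on log₁₀(lag) against
the exact term set (1, pO2², pO2·angle, T·pO2, angle², pO2) and
log₁₀(−μmax) against (1, pO2, pO2², aging², pO2·aging, aging·angle); the
aging-time factor is sometimes written "Mat" (maturation) — both spellings
denote aging days, and the ambiguous last μmax term is read as
aging·angle. Columns are norm-scaled before solving so noise-free
recovery is exact to near machine precision; rank deficiency raises an
error naming the confounded terms. Real regression coefficients are never
hard-coded: they are always estimated from data. Note the lag term set has
no pure-T or T² term — temperature acts only through T·pO2 — which
constrains what factor patterns the model can express (see the synthetic
truth below).

## Staged calibration of (S, Ea)

Stage 1 scans S ∈ {1, 2, 3, 4} × Ea ∈ 25–40 kJ/mol (step 2.5) on a
100-node mesh, pooling squared residuals over all storage conditions with
equal weight (no per-condition weighting; Ea is refined jointly across
conditions, not per condition). Predictions are interpolated linearly in
time to the observation stamps. Stage 2 refines Ea by Levenberg–Marquardt
at the two best S values. Stage 3 recomputes the per-condition
root-of-sum-of-squares table on the 400-node mesh at each refined
candidate and returns the minimizer of the mean, ties toward smaller S.
Trajectories are cached per (Ea, mesh, condition) since S only affects the
color map, which makes the scan cheap. A continuous-S refinement is
deliberately not the default (integer candidates match how the threshold
is used in practice). If the data are flat or the scheme inert the scan is
flagged insensitive rather than failing.

## Bundled stand-in scheme

The full literature oxidation network (22 reactions) is not distributed
with this package; the scheme is an input file, and the bundled default is
a minimal 4-reaction surrogate: oxygenation Mb + O₂ → MbO₂
(2.72×10⁻³ (mol·m⁻³)⁻¹ s⁻¹), deoxygenation MbO₂ → Mb + O₂ (1×10⁻⁴ s⁻¹),
autoxidation MbO₂ → MMb (7.14×10⁻⁷ s⁻¹), and a weak non-enzymatic
reduction MMb → Mb (1×10⁻⁸ s⁻¹), all at 20 °C. The oxygenation equilibrium
K = k_ox/k_deox ≈ 27 (mol·m⁻³)⁻¹ sets the bloomed fraction
f = K·[O₂]/(1 + K·[O₂]) (≈0.88 under 20 % O₂, ≈0.97 under 100 %); the
surface red pool then drains at ≈ k_autox·f, which is how higher O₂ both
deepens the bloom and delays browning. `scripts/tune_default_scheme.py`
(committed) bisects k_autox so the color plateau at 2 °C / 20 % O₂ /
S = 2 / Ea = 32.5 kJ/mol ends at 10 days, and reports the resulting
temperature ordering and the O₂ delay (≈2.2 days for the 0.6 crossing at
2 °C). Since myoglobin is tracked as fractions, the O₂ consumed/released
by (de)oxygenation is in fraction units against a mol·m⁻³ field; the units
are mixed by construction, documented per reaction in the scheme file, and
acceptable for a stand-in whose role is qualitative fidelity.

## Synthetic data generator

`make_design("definitive-screening")` is the standard 13-run, 4-factor,
3-level definitive screening design: fold-over pairs of the rows of the
order-6 Paley conference matrix (first four columns) plus a center run,
mapped onto the levels T ∈ {2, 6, 10} °C, O₂ ∈ {0, 20, 100} %, aging ∈
{0, 7, 14} d, angle ∈ {0, 45, 90}°. `synth_kinetics` composes the factor
regressions with the Gompertz curve at 15-min sampling over 15 days
(1441 points) and adds i.i.d. Gaussian noise (default σ = 0.02 on the
a*/a*₀ scale, a plausible repeatability for image-based colorimetry),
clipped to [0, 1.05]; `synth_from_rd` instead runs the reaction–diffusion
model and color map, which is what the calibration self-consistency suite
uses. Both are deterministic given the seed.

The default truth coefficients are fabricated and labelled synthetic in
all metadata. They encode: lag ≈ 8 d at 2 °C / 20 % O₂, decreasing with
temperature at both O₂ levels; lag increasing from 20 % to 100 % O₂ at
every design temperature (≈ +4.7 d at 2 °C, ≈ +0.1 d at 10 °C); ≈ 2 d lag
for anoxic packs; decay rates of 3.8–6 a*-units/day. The T·pO2-only
temperature term forces a trade-off: a strong temperature effect at 20 %
O₂ implies a five-fold stronger one at 100 % O₂, which would push
high-oxygen lags outside the realistic [1, 14] d window, so the defaults
deliberately use a moderate temperature effect rather than a dramatic one.
Every design run is validated to keep lag within [1, 14] d.

What the generator does **not** emulate: spatial heterogeneity of the cut
surface (real measurements select a repeatable sub-area), autocorrelated
or heteroscedastic measurement error, microbial or enzymatic effects on
color, or any coupling between aging/angle and the chemistry. Passing the
recovery suites therefore demonstrates correctness of the estimation
machinery under the stated noise model, not predictive validity on real
meat — for that, users must supply measured kinetics and a literature
reaction scheme.

## Problem sizes used in the shipped studies

The calibration self-consistency study uses all six (T × O₂) conditions at
hourly sampling over 15 days (361 points per condition), a 100-node mesh
for scan/refinement and 400 nodes for verification. The noisy-recovery
studies use 20 seeded replicates for the Gompertz fits (15-min sampling)
and reduced meshes (30–60 nodes) with 2-hourly sampling for the noisy
calibration replicates, which is sufficient because the surface kinetics
are mesh-insensitive (above). The oxygen-delay comparison integrates 25
days so both atmospheres cross a*/a*₀ = 0.6.

## Known limitations

* The stand-in scheme is not a literature reaction network; its constants
  are tuned to qualitative targets and its absolute predictions carry no
  quantitative authority.
* A single Ea for all reactions is a simplification; per-reaction Ea is
  out of scope.
* The sharp threshold S produces an abrupt plateau-to-decay transition;
  the logistic variant softens it but its width is not calibrated.
* Dirichlet surface O₂ ignores any surface mass-transfer resistance and
  film permeability; with it, surface color is insensitive to mesh
  refinement for the bundled scheme.
* The Gompertz lag regression cannot represent temperature effects at
  0 % O₂ (every temperature-bearing term contains pO2).
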