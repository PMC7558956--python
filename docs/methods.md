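# Methods

`gutfa` predicts the fraction of an oral dose absorbed (Fa) for poorly
soluble *free weak base* drugs, bottom-up, from physicochemical inputs
(pKa, logP_oct, intrinsic and biorelevant solubility, molecular weight,
particle size) and a species/prandial-state physiology table. Everything is
closed form — no differential-equation integration and no randomness — so a
prediction is a transparent chain of hand-checkable numbers.

## Model

### Gastric stage

Gastric fluid is HCl at an initial pH (human fasted 2.0, fed 2.7; dog 2.0;
any acid-reducing agent, ARA, sets 6.0). A dissolving free base consumes
protons, and because HCl is unbuffered this moves the pH. Two corrections are
applied before computing gastric dissolution:

* **Bulk equilibrium pH.** Charge neutrality with the base's pH-solubility
  profile `S(pH) = S0 (1 + [H+]/Ka)` gives a quadratic in `[H+]`,

  `[H+]^2 (1 + S0/Ka) − [H+]([H+]_ini − Kw/[H+]_ini) − Kw = 0`,

  whose positive root defines pH_eq and the gastric saturation solubility
  S_ST. The root is computed with the cancellation-safe quadratic formula and
  is verified against sign-change bisection on the unrearranged balance in
  the test suite (1e−9 relative, 1000 random parameter sets).

* **Solid-surface pH (Mooney–Stella film model).** At the particle surface
  the acid–base reaction outruns proton diffusion, so the surface sits at a
  higher pH than the bulk and the *dissolution-driving* solubility is the
  surface one. A steady-state film flux balance (protonated base out, H+ in,
  OH− out, dissolved drug treated as a bulk sink) gives a second quadratic,

  `(D_drug S0/Ka + D_H) [H+]_s^2 − (D_H [H+]_b − D_OH Kw/[H+]_b) [H+]_s − D_OH Kw = 0`.

  With equal diffusivities this collapses exactly to the bulk-equilibrium
  quadratic — an internal consistency oracle asserted in the tests. D_H =
  9.31e−5 and D_OH = 5.28e−5 cm²/s (standard aqueous values) and
  Kw = 1e−14 are configuration constants; the surface pH of a strongly
  dissolving base is moderately sensitive to the D_H/D_drug ratio, which is
  why the cinnarizine surface-solubility check is asserted only within a
  3-fold band.

Dissolution uses the initial-rate Noyes–Whitney coefficient summed over a
log-normal particle-size distribution (σ of ln r = ln 2, 20 bins over ±3σ;
`E[r^−2]` of the discretization converges to <1% of the closed-form moment
at 20 bins):

`k_diss = (3 D S_surface / ρ) Σ_i f_i / r_i²`, ρ = 1.2 g/cm³.

The mass-weighted per-bin reading `Σ f_i/r_i²` is used; the reciprocal
second-moment reading is available behind `kdiss_sum_mode` for sensitivity
work. With first-order gastric emptying (mean transit `T_ST = T_{1/2}/ln 2`)
the fraction dissolved before transit is

`Fd_ST = 1 / (Do_ST + 1 + 1/Dn_ST)`,
`Do_ST = Dose/(S_ST V_ST)`, `Dn_ST = k_diss,ST · T_ST`,

labelled solubility-limited (SL) when the SL closed form `1/Do` binds
tighter than the rate-limited form `Dn/(1+Dn)` (i.e. `Do > 1 + 1/Dn`), else
dissolution-rate-limited (DRL). Three gastric scenarios are exposed:
(A) no gastric dissolution, (B) all solubilities at the initial bulk pH,
(C) S_ST at pH_eq and S_surface at the Mooney–Stella surface pH. (C) is the
physically motivated default; (A) and (B) bracket it, and the implementation
guarantees Fa(B) ≥ Fa(C) ≥ Fa(A) row-wise.

### Intestinal stage

Dissolved capacity splits into an aqueous monomer part, from the
pH-solubility profile at intestinal pH, and a bile-micelle part linear in
bile concentration. The micellar increment per mM bile is anchored to the
state-matched measured biorelevant medium (fed-state medium for fed
predictions when available, dog-bile-level medium for dog scenarios).  Two
fallbacks: a fed prediction anchored on a fasted medium multiplies the
per-bile increment by `fed_bile_scale = 1.5` (fed media solubilize more per
bile molecule; the three drugs with both media measured give ratios 1.2–4.9),
and a drug with no biorelevant measurement at all uses the micelle–water
partition correlation `log10 Kbm [M⁻¹] = 0.74 logP_oct + 2.29` applied to
the *intrinsic* solubility (the unionized species is what partitions).

Effective permeability is a series composition:

* epithelial: `P_ep = f_mono (f0 P_trans0 + P_para)` with `f0` the unionized
  fraction at intestinal pH and `f_mono = S_aq/S_SI` the non-micellar
  fraction (micelle-bound drug neither crosses the membrane nor the tight
  junction). `P_trans0` comes from a measured cell-monolayer Papp divided by
  the assay-pH unionized fraction when one exists (enoxacin, palbociclib),
  otherwise from `log10 P_trans0 = 0.94 logP_oct − 5.2`. The paracellular
  term uses Renkin sieving of the equivalent-sphere molecular radius through
  the species' pore-radius parameter with an electrochemical enhancement of
  2.39 for the cation, scaled by 15 cm⁻¹.
* unstirred water layer (UWL): film diffusion of dissolved drug with the
  monomer-fraction-weighted diffusivity (monomer D from
  `9.9e−5 MW^−0.453` cm²/s; micelle D 7.4e−7 cm²/s).

`P_eff = 1/(1/P_UWL + 1/(VE·P_ep))`; the permeation number multiplies by the
plicate expansion and tube geometry, `Pn = (2 DF / R_GI) PE P_eff T_SI`.

**Particle drifting.** When undissolved particles are present (dose number
above one) they are carried into the UWL and keep dissolving there, acting
as a distributed source that can raise the UWL flux far above the plain film
value — without this the strong dose- and size-dependence of the
saturation-limited predictions cannot be reproduced. The implementation uses
the reaction–diffusion enhancement

`P_UWL = sqrt(D K) coth(h sqrt(K/D))`,
`K = C_pd · (r50/r_ref)^{2/3} · k_diss,SI · C_solid / S_SI`,

which reduces to `D/h` as the solid load vanishes. `C_pd = 2.2` is the
physiology's particle-drifting coefficient; the `(r50/r_ref)^{2/3}` factor
(r_ref = 40 μm) is an empirical drifting efficiency — larger particles are
supplied to the wall more effectively (sedimentation-like transport),
partially offsetting their slower per-mass dissolution. The exponent and
reference radius were fixed once by regressing the enhancement implied by
the published benchmark table against the Thiele modulus and particle radius
(r² = 0.95 over 80 saturated rows) and are not adjusted per drug.

The fraction absorbed in the small intestine is the closed-form
dose/dissolution/permeation-number equation

`Fa_SI = 1 − exp(−1 / ((1/Dn_SI + Do'_SI/Pn_SI) · Tn_SI))`, `Do' = max(Do, 1)`,

with `Dn = k_diss,SI T_SI`, `Tn ≡ 1` (Dn and Pn are rate × transit-time
products; this convention makes the equation reduce to the standard closed
form and reproduces the published no-gastric-dissolution column). Intestinal
dissolution uses bulk S_SI with the weighted diffusivity — no surface-pH
correction, which is second order at pH 6–7 for these bases. The rate
limiting step is classified as permeability- (epithelial or UWL),
dissolution-rate- or solubility-permeability-limited from the relative sizes
of Dn, Pn and Do.

### Composition and ARA DDI

Drug dissolved in the stomach is assumed not to re-precipitate before
absorption (the model therefore returns a *possible maximum* Fa), gastric
absorption is neglected, and

`Fa = Fd_ST (1 − e^{−Pn_SI}) + (1 − Fd_ST) Fa_SI`.

The ARA interaction is the ratio of scenario-C Fa with gastric pH 6 versus
the normal-acidity control, assuming exposure proportional to absorption —
a worst-case DDI estimate (first-pass nonlinearity, e.g. ketoconazole, is
not modelled).

## Inputs and calibration

The packaged tables transcribe the published benchmark: 15 drugs, 8
physiology blocks, 95 dose scenarios (85 with a literature-derived observed
Fa, 22 ARA pairs with observed AUC ratios), plus the published predicted
columns carried as reference values for validation. Observed Fa/AUCr are
literature constants, not recomputable here.

Free coefficients of the intestinal closure (P_trans0 correlation,
paracellular scale, fed-state bile factor, drifting efficiency) were
calibrated **once** against the published no-gastric-dissolution prediction
column — which isolates the intestinal stage — and then frozen; no per-drug
fitting. After freezing, 94/97/98% of the 95 published scenario A/B/C
predictions are regenerated within 1.25-fold (maximum deviation 1.64-fold,
an aprepitant dog row).

## Numerical choices

* Quadratics solved via the citardauq form when `b > 0` to avoid
  cancellation (`b² ≫ 4ac` is common: strong acid, tiny Kw).
* Monodisperse binning (`ln_sd = 0` or one bin) short-circuits the
  discretization; bins are geometric midpoints of equal-width ln-r intervals,
  masses renormalized over the ±3σ window.
* `Fa_SI` is continuous at the `Do = 1` floor by construction.
* All intestinal dimensionless numbers are computed in seconds; transit
  times in the physiology table are minutes and converted explicitly.
* Degenerate inputs (non-positive concentrations, pH outside (0, 14),
  mismatched ARA pairs) raise typed `DomainError`/`ValidationError` rather
  than propagating NaNs.

## Limitations

* Monoprotic free bases only: no salt forms (Ksp-controlled dissolution),
  no polyprotic chemistry, no buffered gastric media, no common-ion
  suppression. The cinnarizine pH–solubility profile is known to deviate
  from the ideal Henderson–Hasselbalch form by several-fold at pH ≈ 2.5;
  the model inherits that error.
* No intestinal particle growth, nucleation or precipitation: predictions
  are upper estimates of Fa, and predicted AUC ratios are worst-case DDI
  estimates.
* The particle-drifting efficiency exponent is an empirical closure chosen
  against the published benchmark, not a derived hydrodynamic result; it
  should be revisited if the model is applied far outside the 0.1–100 μm,
  0.01–10 mg/mL solid-load range represented there.
* Transporters, gut-wall metabolism and regional pH gradients are not
  modelled; dogs' high gastric pH variability is represented by a single
  fixed value.
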