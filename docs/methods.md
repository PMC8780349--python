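# Methods

## Model structure

Skin is represented as three stacked homogeneous slabs — stratum corneum
(SC), viable epidermis (ED) and dermis (DE) — each described by a
thickness h (µm), a lumped diffusivity D (cm²/h) and a layer/water
partition coefficient K. One-dimensional Fickian transport couples the
slabs; at interfaces the chemical activity a = c/K is continuous while
concentration jumps by the partition ratio. The upper boundary is the
donor vehicle, the lower boundary a perfect receptor sink (receptor fluid
is assumed chosen to match dermal solubility and diffusivity, which is the
standard infinite-sink arrangement in Franz-cell work). Outputs are the in
vitro permeation test observables: receptor-entry flux yJ(t) and
cumulative receptor amount yQ(t).

Processes deliberately outside the model: follicular shunt transport, skin
surface pH, dermal blood flow and any systemic (in vivo) disposition,
vehicle evaporation, and metabolic clearance in viable skin. The model's
scope is in vitro flux prediction.

## Donor regimes

If the applied dose exceeds what the vehicle film can dissolve
(dose > solubility × film thickness), the donor holds excess solid and its
activity is pinned at saturation for the whole run (*saturated* regime);
otherwise the donor is a finite, well-mixed, depleting layer. For the
packaged scenarios this classifies the two aqueous-buffer experiments
(diamorphine, buprenorphine; doses far above their water solubilities) as
saturated and the ethanol phenobarbital experiment as finite.

For ionizable compounds in a saturated donor, the permeating neutral
species sits at its intrinsic saturation activity regardless of vehicle
pH (excess solid buffers the neutral concentration), so the non-ionized
fraction does **not** scale the SC permeability by default
(`qspr.ionize_permeability = false`). It does scale the lipid term of
K_sc/w (`qspr.ionize_lipid_partition = true`), the standard pH-partition
assumption for storage capacity. Both behaviours are configuration
switches.

## SC transport closure

Three QSPRs with published uncertainty half-widths drive the SC:
log₁₀k_trans (trans-bilayer permeability, from molecular weight; ±1.26),
log₁₀PC_pro/w (corneocyte protein/water partition, from log K_ow; ±0.32)
and log₁₀K_lip/w (intercellular lipid/water partition, from log K_ow;
±0.434). The SC is treated as a homogeneous pseudo-phase:

* whole-SC permeability `P_sc = k_trans · K_lip/w / N_bilayers`, with
  `N_bilayers = 70` lipid bilayers in series (a geometry constant; any
  constant offset is absorbed when log₁₀k_trans is fitted inside its
  ±1.26 band);
* `K_sc/w = φ_w·hydration + φ_pro·PC_pro/w + φ_lip·K_lip/w·f_ni`, with
  fully hydrated phase fractions φ_w = 0.60, φ_pro = 0.325, φ_lip = 0.075,
  held age-invariant (infant and adult SC show similar lipid/protein
  composition);
* `D_sc = P_sc · h_ref / K_sc/w`, where h_ref is the **adult reference**
  hydrated SC thickness (43 µm). Anchoring D_sc to the reference rather
  than the subject's thickness makes it a material property: steady flux
  then scales as 1/h_sc, which is the mechanism by which thinner neonatal
  SC produces higher flux. (If D_sc rescaled with the subject's h_sc,
  steady flux would be thickness-invariant and age could not matter.)

ED and DE are tortuous aqueous gels: D = D_aq/τ with
log₁₀D_aq(cm²/s) = −4.15 − 0.655·log₁₀MW and tortuosity τ = 3;
K_ed/w = K_de/w = 0.7 (near-aqueous tissue, with albumin-accessible-volume
effects folded into the constant). The evaluated outputs are dominated by
the SC parameters, so these simple closures suffice and are configurable.

## Default geometry

* h_sc = 43 µm (fully hydrated, in vitro), h_ed = 60 µm.
* h_de = 500 µm: dermatomed (split-thickness) skin as mounted in
  Franz-cell experiments. Full-thickness dermis (~2.5 mm) would add a
  dermal transit lag of several hours that is incompatible with the
  12–72 h accumulations these experiments report; split-thickness
  preparation is the usual IVPT practice for exactly that reason.
* Donor film depth 10 mm (~1 mL/cm² of liquid donor, standard solution
  dosing). This matters only in the finite regime, where it sets the donor
  concentration; at this depth the phenobarbital donor depletes < 2% over
  12 h, consistent with the reported steady-state flux.

## Maturation curves

Each age-dependent parameter is a child:adult ratio as a function of
postnatal age in days, pinned to exactly 1 at and beyond a cap age:

| parameter | form | curve | cap (d) |
|---|---|---|---|
| SC thickness (model 2, default) | power | 2.662×10⁻⁷·Age^1.878 + 0.724 | 1604 |
| SC thickness (model 1, optional) | polynomial | 2.401×10⁻⁷·Age² − 99.43·Age^0.002071 + 101.4 | 1510 |
| epidermis | Hill | 0.366·Age^5.363/(18.702^5.363 + Age^5.363) + 0.634 | — |
| dermis | sigmoid | 1.093·Age/(8974 + Age) + 0.407 | 9883 |
| SC hydration | polynomial | −0.344·Age^0.245 − 17.585·Age^−0.0171 + 18.530 | 1182 |

Numerical choices at the edges:

* the hydration polynomial diverges as Age → 0 (negative exponent), so
  ages are clamped to ≥ 1 day for that curve; the underlying capacitance
  data start at one day of life;
* the dermis formula reaches only ≈ 0.98 at its cap age; the jump to 1 is
  implemented exactly as printed rather than smoothed;
* the printed SC model-2 coefficients actually cross 1 at ≈ 1597 d,
  slightly before the printed 1604 d cap, so the curve may exceed 1 by up
  to 0.003 in that window before the cap pins it — a printed-precision
  seam, asserted (with that allowance) rather than hidden.

SC model 1 was fitted including a neonatal dataset whose SC readings
exceed adult values, contradicting all other sources; model 2 (excluding
it) is the default, model 1 is retained behind `maturation.sc_model`.

Hydration mechanistically scales the SC water phase fraction φ_w. In the
in vitro evaluation the SC is fully hydrated, so
`maturation.in_vitro_full_hydration = true` forces the hydration ratio to
1 there; in vivo-style runs can disable this.

## Curve fitting and model selection

Candidate forms (sigmoid a·Age/(b+Age)+c; Hill a·Ageⁿ/(bⁿ+Ageⁿ)+c;
polynomial a·Ageⁿ+b·Age^m+c) are fitted to ratio data by unweighted
nonlinear least squares on the ratio scale (no log transform, no weights),
multi-started (default 20) from boxes spanning the published coefficient
magnitudes, with log-uniform sampling for scale-like parameters (age
scales in [1, 10⁴] d, exponents in [0.01, 8]; the polynomial's second
exponent extends to [−1, 8] to admit the hydration curve's negative
exponent). The form with the lowest mean squared leave-one-out prediction
error wins; ties break to fewer parameters, then lower RSS. The cap age of
a fitted model is the root of curve = 1, solved numerically.

An identifiability caveat established by simulation: with Hill steepness
n ≈ 5.4 and additive noise σ = 0.05, the likelihood in n is nearly flat
above n ≈ 5 (curves differ by less than the noise), so n cannot be
recovered to 15% at that noise level even with 40 well-placed points; at
σ = 0.02 all of (b, c, n) are recoverable within 15%. The parameter-
recovery test therefore runs at σ = 0.02, and a separate check at σ = 0.05
asserts curve (prediction) recovery to ~1.5 noise SDs instead of
coefficient recovery.

## Adult SC-thickness uncertainty

The 19 literature site-mean SC thicknesses give a lognormal CV of 0.43
(n−1 variance of natural logs; all 19 rows treated as independent values).
Applied to the hydrated adult mean of 43 µm via σ² = ln(1+CV²),
µ = ln(mean) − σ²/2, this yields Lognormal(µ = 3.68, σ² = 0.17). A child's
SC thickness is sampled by drawing from this adult distribution and
multiplying by the SC maturation ratio at the child's age. Only h_sc is
sampled; h_ed and h_de scale deterministically.

## Extrapolation workflow

S1: parameterize the adult model (age 30 y = 10,950 d; all maturation
ratios at parity). S2: fit the QSPR triple, each parameter inside its
published box, to the observed adult terminal flux and final receptor
accumulation by minimizing the sum of squared relative errors, multi-start
(default 10; the first start is the nominal point, the rest uniform in the
box). Three parameters against two observations is under-determined: the
contract is output-matching, and near-tied objectives resolve to the
solution closest to nominal. S3: n = 100 simulations at the child's age,
each with a freshly sampled SC thickness; report the geometric mean
(exp of the mean log) of terminal flux and the empirical 2.5th–97.5th
percentile interval. Terminal flux (yJ at the final time) is the default
comparator; a trailing-window regression slope of yQ is also exposed.

Preterm subjects (GA < 37 w) are simulated by postnatal age alone by
default (an optional SC-thickness multiplier exists for exploratory use)
and are excluded, along with two buprenorphine rows showing a ~30-fold
observed spread attributed to experimental error, from hard acceptance
checks; all rows appear in the evaluation report.

## Numerics

Finite-volume discretization (default 15/15/30 cells for SC/ED/DE) with
interface conductances from half-cell resistances in activity space
(series/harmonic composition). The semi-discrete system is linear and
time-invariant, and the capacity weighting W = diag(dx·K) symmetrizes it,
so the solver diagonalizes the weighted conductance Laplacian once
(`scipy.linalg.eigh`) and evaluates concentrations, flux and its running
integral *exactly* at the output times — no time-stepping error, no
stiffness constraints. Verified against the classical single-membrane
closed forms (steady flux K·D·C/h and lag h²/6D, to 0.02%) and an
independent explicit finite-difference reference (1%). Mass balance closes
to machine precision; the ledger still computes it per run as an
implementation check with a 10⁻³ acceptance gate. Rounding-level negative
concentrations are rejected beyond a 10⁻⁴ relative tolerance; flux is
clipped at zero and yQ made monotone at the 10⁻⁹ relative level.

## Sensitivity analysis

Normalized central-difference coefficients S = (ΔY/Y)/(ΔP/P) at ±10% for
both outputs, over the nine lumped parameters {D, K, h} × {SC, ED, DE},
perturbing the lumped values directly (so thinning h_sc does not also
change D_sc). A parameter is *age-sensitive* when |S_child − S_adult| ≥
0.15. In the SC-membrane limit the analysis reproduces S(D_sc) ≈ +1,
S(h_sc) ≈ −1.

## Synthetic ratio data

The generator emits curve value + additive Gaussian noise (floored at
0.01) at caller-chosen ages — the stand-in for literature child:adult
ratio scatter used in tests and demos. It emulates the curve shapes and
realistic noise (σ ≈ 0.02–0.05) but not the real literature's features:
uneven age coverage, per-study adult denominators, multi-subject pooling,
or site heterogeneity. Passing fit/selection tests therefore demonstrates
correctness of the estimation machinery, not that the published curves
would be recovered from the original heterogeneous literature data.

## Problem sizes used in checks

Acceptance-style runs use the study's own scale: 10-start adult fits, 100
Monte Carlo samples per neonatal prediction, 50-replicate LOOCV selection
studies on 12-point datasets, and 40-point parameter-recovery fits. The
full pipeline (three adult fits + three 100-sample predictions) completes
in well under a minute on one CPU thanks to the spectral solver.

## Known limitations

* The SC pseudo-phase closure is a deliberate simplification of
  brick-and-mortar SC microstructure; absolute nominal fluxes carry the
  full QSPR uncertainty and the model relies on the adult fit (S2) to
  absorb structural bias. Extrapolations are therefore relative (child vs
  adult), anchored to measured adult data.
* Only SC thickness carries sampled uncertainty; inter-individual
  variability in other parameters is not represented, so the 95% intervals
  understate total biological variability.
* The finite-donor regime depends on the assumed donor film depth, which
  IVPT reports rarely state.
* Preterm physiology is not modelled beyond postnatal-age scaling.
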