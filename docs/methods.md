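# Methods

## Model structure

The model describes a non-binding monoclonal antibody in the rat with 13
ODE states, all amounts in nmol, concentrations in nM (amount / volume),
volumes in L, flows in L/h, time in h.

**Systemic block.** Plasma exchanges with a lumped rest-of-body vascular
compartment at plasma flow Q_t (return flow Q_t − L_t) and with brain
vasculature at Q_b (return Q_b − L_b). Tissue vascular → tissue ISF is
paracellular convection (1 − σ_TV)·L_t·C; tissue ISF drains to lymph at
(1 − σ_TL)·L_t·C; lymph returns to plasma at L_t + L_b. The endosomal
sub-model takes drug up from the vascular side at k_CLupT·V_endo·C.
Inside the endosome, free drug binds FcRn (k_on·C_free·C_FcRn·V_endo,
dissociation k_off) or is degraded at k_deg; the FcRn complex is
exocytosed at rate k_CLupT, a fraction FR returning drug to the vascular
side and 1 − FR delivered to tissue ISF, with receptor recycled to the
free pool either way. Free receptor + complex is conserved at
FcRn_SS·V_endo. Degradation of unbound endosomal drug is the only
elimination in the entire model.

**Brain block.** Brain vasculature feeds the CSF across the BCSFB at
(1 − σ_BCSFB)·Q_CSF·C, split equally between LV and TFV (the choroid
plexus spans the ventricles; the two sub-compartments have equal
volumes), and feeds brain ISF across the BBB at (1 − σ_BBB)·Q_ISF·C.
CSF flows LV → TFV → CM → SAS carrying the cumulated fluid ((Q_CSF +
Q_ISF)/2 out of LV; Q_CSF + Q_ISF thereafter) with no reflection inside
the CSF chain. From the SAS, a unilateral glymphatic flow enters the ISF
at (1 − σ_CSF_ISF)·Q_ISF·C_SAS, and CSF drains to lymph at
(1 − σ_CSF)·Q_CSF·C_SAS. Brain ISF recycles to LV and TFV at
(1 − σ_BISF)·(Q_ISF/2)·C each and drains to lymph at
(1 − σ_BISF)·Q_ISF·C. This bookkeeping balances fluid (ISF receives
Q_ISF at the BBB plus Q_ISF glymphatic, loses Q_ISF to CSF and Q_ISF to
lymph) and reproduces the physiological identity L_b = Q_CSF + Q_ISF,
which the parameter container enforces as an invariant. The brain has no
degradation pathway.

The wiring of the endosomal sub-model and the LV/TFV splits are
reconstructions: the model lineage fixes the constants (FR, k_CLupT,
k_on, k_off, FcRn_SS) but not every flux arrangement, and symmetric
splits were chosen where no apportionment is documented. Consequences of
this freedom are quantified under *Limitations*.

**Dosing.** IV doses are instantaneous plasma boluses (tail-vein
injection time neglected). ICV doses are constant-rate infusions into
the LV whose duration follows from pump arithmetic: dose·BW /
formulation concentration / flow rate (3 mg/kg ≙ 46.5 µl ≙ 15.5 min at
20 mg/ml and 3 µl/min). mg/kg doses convert to nmol at the boundary via
the molecular weight (15 mg/kg, 310 g, 195 kDa → 23.85 nmol).

## Numerical settings

Stiff integration (SciPy LSODA) at rtol 1e-8, atol 1e-10 nmol,
piecewise between dose-event breakpoints so that infusions as short as
5 min are resolved exactly; output on a grid of 0.01 h steps over the
first hour and 0.1 h thereafter. Mass balance holds to better than 1e-6
relative with degradation off, and the FcRn pool is conserved to the
same tolerance. Tiny negative excursions (within solver tolerance) are
clamped to zero.

## Parameter estimation

Two-stage naive-pooled nonlinear least squares, mirroring a local
trust-region solver workflow:

1. **Serum stage.** k_deg (log-transformed) fit to pooled IV serum
   concentrations with proportional residuals (obs − pred)/pred, the
   weights taken from model predictions rather than observations to
   avoid the bias of observation weighting.
2. **Brain stage.** k_deg fixed; σ_BBB, σ_BCSFB, σ_CSF_ISF
   (logit-transformed) fit jointly to CSF and recovery-corrected ISF
   data across all dose groups with unweighted residuals. σ_CSF_ISF is
   only identifiable when both IV and ICV arms are present; with
   single-route data the fit refuses to free it and it must be fixed
   (e.g. to the EGFRvIII-TCB estimate, as done for the DP47 compounds).

Multi-start (5 jittered starts, deterministic in the seed) guards
against local minima; `n_starts=1` reproduces a plain local fit.
Precision is reported as asymptotic CV% = 100·SE/|θ| on the estimation
(log/logit) scale, with SE from (JᵀJ)⁻¹·s², s² = SSR/(n − p). The
residual variance is estimated post hoc from residuals, not jointly.
Observations below the assay LLOQ (2.5 ng/ml ≙ 0.0128 nM at 195 kDa)
and the −0.5 h pre-dose samples are excluded from all objectives.

On noise-free synthetic data the procedure recovers the generating
values to better than 0.5% on the estimation scale (exercised in the
test suite).

## Non-compartmental analysis

Linear-trapezoid AUC(0–t_last), Cmax and Tmax (earliest time on ties)
per animal; group summaries as mean ± sample SD; cross-matrix exposure
ratios in percent formed from group-mean AUCs. BLQ values are excluded
rather than zero-imputed (zero-imputation would drag the AUC toward the
assay floor); dialysate values are recovery-corrected before any
exposure metric; microdialysate samples are stamped at their
collection-interval midpoints.

## Pathway analyses

Source apportionment integrates the two instantaneous ISF-input fluxes
(1 − σ_BBB)·Q_ISF·C_serum and (1 − σ_CSF_ISF)·Q_ISF·C_SAS by linear
trapezoid over 0–48 h and normalises; the serum-route flux uses the
serum concentration as defined, although the ODE influx is driven by
brain-vascular concentration — the two track within 1% once distribution
is complete. The exposure share is ISF/serum% = AUC_ISF/(AUC_serum +
AUC_ISF)·100, and the scaled contributions multiply the route shares by
it. Shares are dose-scale invariant (disposition is linear at study
concentrations; the endosomal free-drug concentration stays far below
FcRn_SS) and converged under 2× grid refinement; ICV shares are
reported for the 3 mg/kg schedule, the choice being immaterial under
that invariance. The endosomal elimination apportionment (brain vs
rest-of-body share of total degradation) is provided as a
model-agnostic utility over supplied endosomal trajectories, since this
reduced model deliberately carries no brain endosome.

## Synthetic-data generator

The generator emulates the in-vivo study design: three EGFRvIII-TCB arms
(15 mg/kg IV, 3 and 1 mg/kg ICV), n = 5 animals each, 310 g body
weight; serum and cisterna-magna CSF sampled at −0.5, 0.5, 1, 3, 4.5,
6, 12, 24, 48 h; prefrontal-cortex dialysate as 30-min interval
averages over 0–8 h and 4-h averages over 8–48 h, scaled by the
in-vitro probe recovery. Residual error is multiplicative mean-one
log-normal on serum (default CV 15%) and additive zero-truncated normal
on CSF and dialysate (defaults 10 nM and 0.5 nM respectively — chosen
once to visually match the scatter of the published individual-animal
profiles; the true residual magnitudes are not printed anywhere).
Negative draws truncate to zero; anything below the LLOQ is flagged
censored. Generation is byte-reproducible from the seed. Between-animal
parameter variability is off by default, consistent with naive-pooled
estimation.

What the generator does *not* emulate: inter-animal physiological
variability, probe drift or in-vivo recovery differences, surgical
failures, dropout, or assay calibration-curve nonlinearity. Passing
parameter-recovery tests on these data therefore demonstrates
correctness of the estimation machinery under the assumed error model,
not robustness to the full messiness of animal data.

## Design choices on open points

- **CSF production split** between LV and TFV: 50/50 (equal
  sub-compartment volumes, no published apportionment).
- **ISF recycling split** to LV vs TFV: 50/50, same reasoning.
- **k_on units**: the FcRn association constant is treated as
  1/(nM·h); the association flux k_on·C_free·C_FcRn·V_endo then has
  units nmol/h, which is the only dimensionally consistent reading.
- **Dialysate semantics**: flow-weighted probe sampling is approximated
  by the interval time-average of ISF concentration; recovery is
  multiplicative and time-invariant (a single in-vitro value per
  compound is available).
- **Sensitivity analysis**: L_b is treated as derived (Q_CSF + Q_ISF)
  when perturbing the brain fluid flows so every perturbed parameter
  set satisfies the fluid-balance invariant; reflection coefficients
  are perturbed with a step shrunk to stay inside (0, 1).
- **Observation container**: a validated pandas DataFrame schema
  (subject, group, route, dose_mgkg, matrix, time_h, conc_nM, bloq)
  rather than per-row objects.

## Limitations

- The ISF outflow reconstruction (recycling to two ventricle segments
  plus lymphatic drainage, all reflected by σ_BISF) sets the effective
  ISF solute clearance at (1 − σ_BISF)·2·Q_ISF = 4.8e-5 L/h. The
  published exposure shares are consistent with a smaller effective ISF
  outflow (~Q_ISF); with the wiring implemented here the predicted
  ISF/serum exposure shares are 0.79% (IV) and 0.99% (ICV), lower than
  the published 1.4%/1.6%, while the route apportionment (99.9% BBB
  after IV; ~81/19 serum/CSF after ICV vs published 77.6/22.4) is
  reproduced. Route shares are robust to this choice because it scales
  both routes' downstream sink equally; absolute ISF exposure is not.
- Zero-truncated additive error is not mean-preserving where the signal
  is comparable to the noise SD. At the default dialysate noise level
  this inflates low ISF observations and biases σ_BBB toward more
  uptake (≈ −6% median on the logit scale over 20 replicates) — a
  property of the assumed error model at low SNR, not of the optimizer;
  it disappears as the additive SD shrinks.
- The ICV arms have dose-dependent infusion durations (pump
  arithmetic), so their dose-normalised CSF washout curves are shifted
  by ~5 min and do not superimpose pointwise during the steep washout;
  superposition holds to solver tolerance once the input shape is
  matched, and integrated quantities (AUCs, route shares) are
  dose-invariant to 0.1%.
- Physiological flows (Q_CSF, Q_ISF) carry real uncertainty and may
  change with disease; all values here are healthy-rat constants.
- No target-mediated disposition (the tool compounds do not bind rat
  antigens), no brain endosomal FcRn sub-compartments, no lambda-z
  extrapolation beyond t_last in the NCA.
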