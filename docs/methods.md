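# Methods

## Model

The package models the maize floral transition with one state variable,
the scaled *ZMM4* mRNA level m(t), driven by binary allele inputs:

    dm/dt = α₁ · (ID1 + α₂·ID1·DLF1 + α₃·VGT1 + β_eff) + ω·m,   m(0) = 0.

The bracketed term is a genotype-specific constant, the *forcing constant*
c = `regulatory_input(genotype, params)`. Assumptions baked into this
form:

- **Binary genetics.** Each genetic element is present (functional /
  early allele = 1) or absent (0); no allelic series, no dosage.
- **Logic gating.** The ID1 main effect carries an implicit unit
  coefficient (it sets the scale of the dimensionless weights); DLF1
  contributes only through the ID1·DLF1 product, so loss of *ID1*
  silences both terms — which is why the *id1* single mutant and the
  *id1 dlf1* double mutant have identical dynamics.
- **Transgene rule.** A *PRO_UBI:ZMM4* line expresses two *ZMM4* copies,
  modelled conservatively as β_eff = 2β.
- **Positive feedback.** ω > 0 summarizes reinforcement of *ZMM4* by
  floral integrators near the commitment point; it makes m(t) exponential
  rather than linear.
- **Run-up only.** Real *ZMM4* expression declines after its peak at the
  transition; the model does not describe that phase. Trajectories are
  meaningful on [0, DTI] and simply keep growing afterwards.
- **No environment.** No photoperiod, temperature or circadian forcing;
  genotype alone sets the trajectory.

The floral transition status is a threshold readout: FTS = 1 once m
reaches `threshold` (default 1.0, the maximum of expression scaled to
[0, 1] across genotypes). The crossing time is the predicted days to
tassel initiation (DTI).

## Parameters

| name | meaning | units | reference value |
|------|---------|-------|-----------------|
| α₁ (`alpha1`) | overall scaling of the gene effects | d⁻¹ (scaled units) | 0.002000 |
| α₂ (`alpha2`) | ID1×DLF1 interaction weight | – | 6.489431 |
| α₃ (`alpha3`) | VGT1 weight | – | 53.204799 |
| β (`beta`)    | basal *ZMM4* synthesis weight | – | 0.821720 |
| ω (`omega`)   | positive-feedback rate | d⁻¹ | 0.086782 |

All five are constrained strictly positive: negative synthesis or
decay-style feedback has no meaning in this model. The large α₃ relative
to α₂ and the unit ID1 effect encodes the dominant influence of the early
*VGT1* allele; the small α₁ relative to ω encodes a dynamic dominated by
the feedback loop. Under the reference vector the panel's predicted
transitions are Gaspe Flint 6.15 d < B73 21.06 d < *dlf1* 37.01 d < *id1*
45.92 d (analytic values).

## Numerics

- **Integrator.** Forward Euler, dt = 0.01 d, horizon t_max = 100 d
  (safely past the latest genotype at ~46 d; 10⁴ steps). Because the ODE
  is linear with constant coefficients, the Euler recurrence
  m_{k+1} = m_k(1 + ω·dt) + c·dt has the exact geometric-series solution
  m_k = (c/ω)((1+ω·dt)^k − 1), which the implementation evaluates
  vectorized; a test pins it to the literal recurrence at 1e-12. The
  analytic solution m(t) = (c/ω)(e^{ωt} − 1) is kept alongside as an
  independent oracle: Euler tracks it to <0.5% at the crossing and the
  error is first order in dt.
- **DTI readout.** The crossing time is interpolated linearly between the
  two bracketing grid points rather than snapped to the grid, so the
  calibration objective is smooth in the parameters (Nelder-Mead degrades
  badly on piecewise-constant objectives). Predicted expression at
  observed sampling times is likewise linear interpolation on the Euler
  grid; at dt = 0.01 the interpolation error is negligible.
- **Horizon exhaustion.** A trajectory that never crosses within t_max
  reports `dti=None` (or raises `HorizonExhaustedError` from
  `predict_dti`); inside the objective such a genotype is charged
  DTIp = t_max, a finite pessimistic surrogate that keeps the objective
  decreasing toward feasibility instead of returning infinities.
- **Degenerate inputs.** Zero forcing (possible only by underflow, since
  parameters are positive) yields a flat trajectory and an unreachable
  threshold, rejected by the synthetic generator and signalled by the
  simulator.

## Calibration

The objective is the unweighted sum SSE = SSE_g + SSE_p of expression and
phenology squared errors. The two terms have mismatched units (scaled
units² vs days²); they are summed with unit weights by design, and a
`phenotype_weight` knob is exposed for users who want to rebalance.

Nelder-Mead runs on log-transformed parameters, which enforces positivity
without bounds. Defaults: objective tolerance 1e-10, simplex tolerance
1e-8, 5000 iterations, 3 restarts with seeded multiplicative jitter
(sd 0.2 in log space) around the incumbent. The default start perturbs a
reference vector coordinate-wise by alternating ×1.5 / ×⅔ factors;
real-data fits should supply their own start. Non-convergence is reported
on the result object, never silent.

Identifiability: the forcing constant is linear in (ID1, ID1·DLF1, VGT1,
β-copy count), so separating α₁, α₂, α₃ and β needs a panel whose design
matrix over those four regressors has rank 4 — checked before every fit.
The four training genotypes (Gaspe Flint, B73, *dlf1*, *id1*) achieve
this minimally, and admit an exact algebraic inversion
(`invert_closed_form`) used as the identifiability oracle in tests:
α₁ = c_dlf1 − c_id1, β = c_id1/α₁, α₂ = (c_B73 − c_dlf1)/α₁,
α₃ = (c_Gaspe − c_B73)/α₁.

A known, quantified bias: fitting Euler-simulated predictions to data
generated from the continuous-time solution shifts α₁ and ω by ≈ ω·dt/2
(0.04% at dt = 0.01) because the Euler map is itself exponential with a
slightly different effective rate. This is far inside the 2% recovery
tolerance and vanishes linearly with dt.

## Synthetic data

No raw expression series, observed DTI values or leaf-count tables were
ever published for this system, so the generator fabricates datasets with
the structure the pipeline assumes, and the defaults define the study
conditions used throughout the tests:

- four training genotypes; 10 sampling times per genotype, evenly spaced
  on [0, t*_g] where t* is the analytic crossing time (real sampling
  schedules were genotype-dependent and are unrecoverable);
- expression = exact closed-form value + additive Gaussian noise
  (default sd 0, i.e. noiseless), clipped to [0, 1]; no raw-fluorescence
  or normalization stage is simulated;
- observed DTI = analytic t* + Gaussian noise (default sd 0);
- TLN linked linearly to DTI: TLN = 12.0 + 0.35·DTI + noise, truncated
  positive. The intercept and slope are this package's own calibration
  choices — picked so B73 (~21 d) carries ~19–20 leaves, a realistic
  temperate maize value — and are not measurements.

For a requested regression quality, `tln_noise_for_r2` inverts the
finite-sample relation E[1−R²] ≈ (n−2)s² / (b²Sxx + (n−1)s²) (ratio of
expected sums of squares under a fixed design). The finite-sample terms
matter: with 4–8 genotype means, OLS absorbs part of the noise and the
realized R² sits well above the naive population value; with the
correction, the mean realized R² over 50 seeds lands within ±0.05 of the
target on both the training and full panels.

What passing tests on these data do **not** show: robustness to the
measurement-noise structure of real expression assays (the Gaussian
additive model is an assumption), to irregular sampling schedules, to
environmental variation in DTI, or to any phyllochron (leaf-appearance
rate) biology behind the TLN link — the linear link is structural, not
mechanistic, so the evaluation stage demonstrates the pipeline, not field
accuracy.

## Design choices on genuinely open points

- **Equation reconstruction.** The exact printed equation of the original
  model is not machine-readable in our source text; the implemented form
  places β inside the α₁ parenthesis, consistent with α₁ described as
  scaling *all* gene effects including basal synthesis, and is validated
  by reproducing the expected genotype ordering and transition times.
- **Threshold semantics.** FTS latches at the scaled maximum 1.0 shared
  across genotypes (not at a per-genotype maximum); exposed as a setting.
- **Reference panel rows.** The published genotype table's two transgenic
  mutant rows contradict their names (apparent ID1/DLF1 column swap). The
  default panel derives allele states from the names (an *id1* background
  has ID1 = 0), matching the non-transgenic single-mutant rows; the
  printed variant is available via `as_printed=True`.
- **Time origin.** t = 0 is planting for every genotype; the package does
  not distinguish planting from emergence.
- **Regression orientation.** TLN is the response and predicted DTI the
  regressor, on genotype means (not per-plant values). R² is symmetric to
  this choice for simple OLS; the slope is not.

## Problem sizes

Test-suite simulations use the defaults above (10⁴ Euler steps per
trajectory, 4–8 genotypes, 20–50 seeded replicates where distributions
are checked); the full suite and the acceptance script each run in well
under a minute of CPU.

## Limitations

Point estimation only — no bootstrap or profile-likelihood uncertainty.
Nelder-Mead is the only optimizer. Whether the reference coefficient
vector is a global optimum of the original data is unknowable without the
unpublished raw measurements, and the original evaluation statistic
(R² = 0.86 against field-observed TLN) cannot be reproduced here for the
same reason; the package demonstrates the structure of that analysis on
synthetic TLN instead.
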