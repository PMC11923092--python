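# Methods

This note records the models implemented in `inteinkit`, their assumptions,
the defaults and numerical choices, and what the synthetic-data round trips
do and do not demonstrate.

## Three-state splicing kinetics

The splicing reaction is modelled as a linear first-order network
A ⇌(k1, k2) BI →(k3) P, where A is the pool of free precursors, BI the
branched intermediate and P the splice product. The model assumes
pseudo-first-order conditions (one precursor in molar excess, so the
bimolecular association is absorbed into k1), no side reactions (N-/C-
cleavage bands are not modelled, only reported if quantified externally),
and a fixed active fraction P_max: the initial condition is
([A], [BI], [P])(0) = (P_max, 0, 0) and mass is conserved at P_max.

The closed form is the eigen-decomposition of the 2×2 rate matrix
[[−k1, k2], [k1, −(k2+k3)]]: with p = k1+k2+k3, q = √(p² − 4·k1·k3), the
decay constants a = (p+q)/2 and b = (p−q)/2 satisfy a+b = p and
a·b = k1·k3. q is real for all non-negative rates because

    p² − 4·k1·k3 = (k1 − k3)² + k2² + 2·k2·(k1 + k3) ≥ 0,

so the trajectories never oscillate. When p² = 4·k1·k3 the two
eigenvalues coincide and the generic form divides by a − b; below a
relative gap of 1e-9 the implementation switches to the analytic repeated-
eigenvalue limit with t·e^(−at) secular terms. The closed form is
validated against an independent stiff-accurate numerical integration
(LSODA, rtol 1e-12/atol 1e-14) to < 1e-8 over random rate draws.

*Inactive precursor and the gel.* The splice-incompetent fraction
(1 − P_max) is aggregated material. The generator's default treats it as
not contributing to the resolved precursor band, which makes the generator
exactly the model's forward evaluation and the round trip a generative
identity; `include_inactive_band=True` instead adds it as a constant
offset on the A band for more literal gel emulation. Fits use the
analytic forms directly, so they apply to data normalised the same way.

*Fitting.* All nonlinear fits are least squares with rates parameterised
on a log scale (positivity by construction), multi-start over log-spaced
initial rates, and convergence tolerances of 1e-12 on cost, step and
gradient. Standard errors are Gauss–Newton (Jacobian) estimates mapped to
the natural scale by the delta method. A tiny fitted k2 is accepted (the
scheme degenerates to the irreversible nested model); runaway-large rates
raise a fit error. Replicate lanes are averaged before fitting; the model
is always anchored at t = 0 with intact precursor even when the first
sampled point is later.

*Yield.* The product/precursor ratio x is a percent ratio
(x = 100·SP/A), so the yield P = 100·x/(100+x) equals 100·SP/(SP+A). The
raw-ratio reading of x would give ~1% yield for equal amounts and is
rejected.

## Biphasic BLI analysis

The two-step conformational-change mechanism N + C ⇌(ka, kd) N·C
⇌(kf, ku) NC is linear at fixed analyte concentration C. With ligand
conservation [C] = [C0] − [N·C] − [NC] the complex pair obeys

    d[N·C]/dt = ka·C·[C0] − (ka·C + kd + kf)[N·C] − (ka·C − ku)[NC]
    d[NC]/dt  = kf[N·C] − ku[NC]

whose eigenvalue pair satisfies σ1+σ2 = ka·C + kd + kf + ku and
σ1·σ2 = ka·C(kf+ku) + kd·ku — both linear in C, which is also the model
diagnostic (`validate_biphasic_model` reports the R² of both
regressions). Dissociation is the C = 0 case with eigenvalues γ1, γ2.

*Phase fitting* uses variable projection: amplitudes are linear given the
exponents, so the search runs over (log σ1, log σ2) only, seeded on a
log-spaced grid. The association constraint D = −(E+F) (response starts
at zero) is built into the basis functions e^(−σt) − 1. Exponents are
reported σ1 ≥ σ2. Fits with σ1/σ2 < 1.05, or with one amplitude
negligible, are re-run as single exponentials and flagged
mono-exponential.

*Extraction* follows the slope recipe: ka from the OLS slope of σ1+σ2 vs
C; kf+ku from the slope of σ1σ2/ka vs C; kd = (γ1+γ2) − (kf+ku);
ku = γ1γ2/kd; kf = (γ1+γ2) − (kd+ku), with γ quantities averaged over
the per-concentration dissociation fits (they are C-independent in the
model). Regressions use free intercepts; the intercepts and R² are kept
as diagnostics. Negative derived rates raise a model-inconsistency error
carrying both regression tables.

*Derived constants.* Ka1 = ka/kd, Ka2 = kf/ku, Ka = Ka1(1+Ka2),
Kd = 1/Ka, kon = ka·kf/(kd+kf), koff = kd·ku/(kd+kf). Note that
koff/kon = 1/(Ka1·Ka2) is a different quantity from Kd: Kd ≤ koff/kon
always, with equality only as Ka2 → ∞. Experimentally reported pairs of
Kd and (kon, koff) therefore need not satisfy Kd = koff/kon.

*Units.* Concentrations are molar internally; the CLI accepts nM with an
explicit flag. The steady-state plateau is averaged over the final 10 s
of association by default (configurable).

## Mechanism simulation

`MechanismSpec` makes the mode explicit rather than inferred: the
pseudo-first-order mode holds C fixed (the sensor picture, ligand [C0] on
the tip), while the mass-conserving mode depletes both partners by mass
action (the solution picture) and is required for the three-step scheme's
long-time limit SP(∞) = min(N0, C0). Integration uses LSODA with
rtol 1e-9 and an absolute tolerance of 1e-12 scaled by the concentration
level, so nanomolar problems integrate as tightly as molar ones.
Conservation is checked to 1e-8 relative after integration and negative
concentrations beyond tolerance are an error, never clipped — negativity
signals solver misconfiguration, and clipping would mask it.

The linked simulation sets kf ← k_total (the folding step is taken as the
rate-determining step measured by the product exponential) and
k_splice ← k3 (the resolution rate of the three-state gel fit), with ka,
kd, ku from the BLI extraction. `apparent_kd_from_occupancy` equilibrates
the two-step scheme over a concentration grid and fits the total bound
fraction to a hyperbola; for the linear scheme the analytic answer is
1/(Ka1(1+Ka2)), which the simulation reproduces to < 1% and which the
test-suite uses as its oracle. This is the most literal reading of
"apparent Kd from simulated binding"; other readouts (e.g. folded complex
only) would give different numbers and are not implemented.

## SEC analysis

Kav = (Ve − V0)/(Vt − V0) with V0 from a void marker and Vt the total bed
volume. The Stokes-radius calibration is OLS of R_ST on √(−log Kav) with
the log taken base 10 (standard SEC practice; recorded in the calibration
metadata). Void-volume elution (Kav ≤ 0) is not interpolable and is
reported with lower-bound semantics ("greater than the largest calibrated
radius"). The apparent-MW calibration's functional form is not uniquely
conventional; it is implemented as a second, independent linear fit of
log10(MW) on Kav, flagged as a convention and configurable.

Fraction integration subtracts a linear baseline anchored on the first
and last 5% of the trace (configurable), lightly smooths (5-point moving
average) only for boundary detection, sets the aggregate/monomer boundary
at the inter-peak minimum between the two most prominent maxima, and
integrates trapezoidally. The void-region (earlier) peak is the
aggregate. Percentages are invariant under uniform rescaling of the
trace, so normalising a chromatogram "to its highest peak" cannot change
them.

Dis-/re-aggregation time courses offer a one-phase exponential
M(t) = M∞ + (M0 − M∞)e^(−kt) (default, appropriate for dilution-induced
disaggregation and the post-lag phase of re-aggregation) and a logistic
M(t) = M∞ + (M0 − M∞)/(1 + e^(k(t − t_mid))) for nucleation-limited
re-aggregation with a lag; both report AIC so the lag hypothesis can be
tested on the data. When the process has a lag, the exponential should be
fitted to the post-lag segment only.

## Thermal stability

The melt signal is truncated at the global maximum of the replicate-mean
curve (the same cut applied to all replicates), because past the peak
protein–dye aggregates quench fluorescence and the logistic no longer
applies. After normalising to the maximum, the four-parameter logistic
Y = Ymin + (Ymax−Ymin)/(1 + 10^((T_M − X)·b)) is fitted with b bounded
positive (increasing sigmoid). The fitted curve passes through
(Ymin+Ymax)/2 exactly at T_M. Fits are invariant under uniform
fluorescence scaling.

## Charge–hydrophobicity classification

Mean net charge R = |#(K,R) − #(D,E)|/length with histidine neutral and
termini ignored (the original CH-plot convention; configurable). Mean
hydrophobicity H maps each residue's Kyte–Doolittle value to [0, 1] via
(kd + 4.5)/9, averages over sliding windows of 5 residues, then averages
the window means — the CH-plot windowing convention, since only the scale
itself is conventionally fixed; the choice is recorded in output
metadata. A sequence is on the disordered side when R exceeds the
boundary value R* = 2.785·H − 1.151; the signed vertical distance R − R*
is reported.

## Synthetic data and what the round trips show

Every generator is seeded (NumPy `default_rng`), returns the data plus a
JSON-serialisable truth record, and is byte-reproducible for a fixed seed.
Defaults encode the standard experimental layouts: a seven-step two-fold
BLI dilution series from 200 nM down to 3.125 nM with 500 s association
and 500 s dissociation sampled at 1 Hz; gel time courses with n = 3
replicate lanes and 5% multiplicative log-normal densitometry noise
(densitometry error scales with band intensity, so zero-signal bands stay
zero); additive Gaussian BLI noise of 0.5% of each trace's own maximal
response (per-channel instrument noise scales with the signal level of
that channel); bimodal chromatograms as Gaussian peaks (exponentially
modified Gaussian optional for tailing); melt curves on a 10–90 °C grid
in 1 °C steps with an optional linear post-peak quench.

The round trips demonstrate *identifiability and correctness of the
estimators under the stated noise models*: noiseless data round-trip to
machine precision (generative identity), and at the default noise levels
the BLI rates recover to a few percent, the active fraction to ±0.01 and
T_M to < 0.2 °C. They do not demonstrate robustness to the systematic
features of real data that the generators deliberately omit: baseline
drift and reference-sensor artefacts in BLI, gel background and band
overlap, non-Gaussian chromatogram peak shapes from column interactions,
or replicate-to-replicate temperature offsets in melt curves. Low
analyte concentrations are genuinely ill-conditioned for biphasic fits —
the fast-mode amplitude approaches the noise floor — so recovery
tolerances should be read as properties of this design (seven
concentrations spanning 64-fold), not of arbitrary designs.

## Problem sizes

The default verification runs use: 100 random rate draws for the
closed-form/ODE check; the full seven-concentration BLI series (1001
points per trace) once noiseless and once at 0.5% noise; 50 random rate
sets on 7-point concentration grids for the equilibrium consistency
check; 12 gel time points with 3 replicates; 600-point chromatograms; and
100 random melt curves (81 points each, one third with the quench
artefact). These sizes keep the full verification under a minute on one
CPU while exercising every code path.
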