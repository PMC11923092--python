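# inteinkit

Kinetic and biophysical analysis for split-intein protein *trans*-splicing
(PTS) experiments: gel-densitometry splicing kinetics, biphasic
biolayer-interferometry (BLI) binding analysis, ODE simulation of the
assembly mechanism, size-exclusion chromatography (SEC) aggregate/monomer
and hydrodynamic analysis, thermal-shift melt-curve fitting, and
charge–hydrophobicity sequence classification.

Split inteins ligate two separately produced precursor proteins by excising
themselves; characterising one means answering several linked quantitative
questions at once. How fast is splicing, and what fraction of the precursor
is actually competent to splice? How tightly and by what mechanism do the
two fragments bind? How much of the precursor is lost to soluble
aggregates, and how quickly do those aggregates form and resolve? How
stable is the assembled complex, and does the fragment's sequence predict
its disorder and aggregation behaviour? `inteinkit` implements the
standard quantitative treatment of each question as a library of
statsmodels-style model objects (`Model(data).fit()` → results with
estimates, standard errors and a `summary()` table), a matching set of
seeded synthetic-data generators with known ground truth, and a thin
command-line interface.

## Models

**Splicing kinetics** (`inteinkit.pts`). Gel band intensities are divided
by molecular weight to obtain mole-proportional abundances. The splice
yield from product SP and limiting precursor A is
`P(%) = 100·x/(100 + x)` with `x = 100·SP/A`. Product formation under a
precursor excess is fitted as `P(t) = P_max(1 − exp(−k_total·t))`, where
`P_max` is the active (splice-competent) fraction. The full three-state
scheme

```
A  ⇌(k1, k2)  BI  →(k3)  P
```

(A: precursors, BI: branched intermediate, P: splice product) is fitted
globally over all three traces using the closed-form solution: with
`p = k1 + k2 + k3`, `q = √(p² − 4·k1·k3)` and decay constants
`a = (p+q)/2`, `b = (p−q)/2`, the trajectories are sums of `e^(−at)` and
`e^(−bt)` terms with `a·b = k1·k3` and `[A]+[BI]+[P] = P_max` conserved.

**Biphasic binding** (`inteinkit.bli`). Fragment association follows a
two-step conformational-change mechanism, N + C ⇌ N·C ⇌ NC. At fixed
analyte concentration C the sensorgram is a double exponential whose
eigenvalues satisfy `σ1 + σ2 = ka·C + kd + kf + ku` and
`σ1·σ2 = ka·C(kf + ku) + kd·ku`. Fitting both phases across a dilution
series and regressing the eigenvalue sums/products on C recovers the four
microscopic rates, then `Ka1 = ka/kd`, `Ka2 = kf/ku`,
`Ka = Ka1(1 + Ka2)`, `Kd = 1/Ka`, `kon = ka·kf/(kd+kf)` and
`koff = kd·ku/(kd+kf)`. A Langmuir fit of plateau responses gives the
steady-state `Kd` independently.

**Mechanism simulation** (`inteinkit.assembly`). The two-step scheme, and
a three-step extension with an irreversible splicing sink NC → SP, are
integrated as stiff-capable initial-value problems in either
pseudo-first-order (sensor) or mass-conserving (solution) mode. The
linked simulation couples measured kinetics by setting `kf = k_total` and
`k_splice = k3`.

**SEC hydrodynamics** (`inteinkit.sec`). Elution volumes become partition
coefficients `Kav = (Ve − V0)/(Vt − V0)`; Stokes radii come from a linear
calibration of `R_ST` against `√(−log10 Kav)` over globular standards and
apparent molecular weights from a separate log-linear calibration.
Aggregate/monomer splits are integrated peak areas; dis-/re-aggregation
time courses are fitted with a one-phase exponential or a logistic
(nucleation-lag) model, compared by AIC.

**Thermal stability** (`inteinkit.stability`). Dye-binding melt curves
are truncated at their fluorescence maximum (aggregation quench),
normalised, and fitted with the four-parameter logistic
`Y = Ymin + (Ymax − Ymin)/(1 + 10^((T_M − X)·b))`.

**Sequence classification** (`inteinkit.sequence`). Mean net charge R and
windowed, rescaled Kyte–Doolittle hydrophobicity H place a sequence
relative to the empirical folded/unfolded boundary `R = 2.785·H − 1.151`.

## Worked example

Generate a synthetic splicing time course (active fraction 0.30, 5%
densitometry noise) and fit the three-state model:

```python
import numpy as np
from inteinkit import pts, synthetic as syn

times = np.concatenate([[0.0], np.logspace(0, np.log10(300.0), 11)])
table, truth = syn.generate_pts_gel(k1=0.02, k2=0.01, k3=0.1, times=times,
                                    active_fraction=0.30, noise_sd=0.05,
                                    seed=1)
tc = syn.gel_table_to_timecourse(table)
fit = pts.fit_three_state(tc)
print(fit.summary())
print(f"t_1/2 of resolution step: {pts.half_life(fit.k3):.1f} s")
```

```
Three-state PTS global fit
==========================
parameter           estimate       std err
k1                 0.0206776       0.00103
k2                 0.0114659       0.00614
k3                  0.100866       0.00391
P_max               0.299238       0.00108
------------------------------------------
decay constants a = 0.1148/s, b = 0.01816/s
t_1/2(k3) = 6.87 s
residual norm  0.01567

t_1/2 of resolution step: 6.9 s
```

The fit recovers the generating rates (k1 = 0.02, k2 = 0.01, k3 = 0.1 /s)
and the 30% active fraction from the noisy bands; the resolution step's
half-life `ln 2 / k3` is the intrinsic splicing speed once the fragments
are assembled.

The same pattern runs from the shell:

```bash
inteinkit synth pts --seed 1 --out gel.csv      # writes gel.csv + gel.csv.truth.json
inteinkit pts fit-3state gel.csv --mass-map masses.yaml
```

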