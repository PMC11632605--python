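# Methods

## Model

`etkinetics` implements a mechanistic model of endothelin-1 (ET-1) kinetics
in humans. ET-1 is a 21-residue vasoactive peptide produced by
endothelin-converting-enzyme (ECE) cleavage of its precursor Big ET-1. It
signals through two receptors — ET_A (vasoconstriction) and ET_B
(vasodilation, natriuresis) — and is *cleared* predominantly by receptor
binding and internalization, mostly via ET_B. Competitive receptor
antagonists therefore have a double action: they block signalling, and they
block clearance, so free ET-1 accumulates and binding through the
non-antagonized receptor can rise.

Three state variables: tissue Big ET-1, and total (free + bound) ET-1 in a
tissue and a central/plasma compartment,

    dBigET/dt         = Prod_BigET − (kcat/Km)·BigET·[ECE]
    Vt·d[ET1]tot,t/dt = Prod_ET1 − Ktp·Vt·[ET1]t + Kpt·Vp·[ET1]p
                        − Kint·Vt·([ET1-RA]t + [ET1-RB]t)
    Vp·d[ET1]tot,p/dt = Ktp·Vt·[ET1]t − Kpt·Vp·[ET1]p
                        − Kint·Vp·([ET1-RA]p + [ET1-RB]p)

where `[ET1]` denotes the *free* concentration. ET-1 production occurs in
the tissue compartment only, as the instantaneous ECE conversion flux
`Prod_ET1 = (kcat/Km)·BigET·[ECE]·Vt` (amount/min), which makes the
Big ET-1 → ET-1 step mass-conservative; `Prod_BigET` is fixed by the
precursor steady state, `Prod_BigET = (kcat/Km)·BigET(0)·[ECE]`.

### Quasi-equilibrium binding

Receptor binding is orders of magnitude faster than production,
distribution and internalization, so free ligand, free receptors and
complexes satisfy algebraic equilibrium at every instant with a single
dissociation constant `K_d` shared by both receptor types. With a
competitive antagonist at concentration `I` (inhibition constants `K_ia`,
`K_ib`), each receptor sees an apparent `K_d·(1 + I/K_i)`:

    [ET1-RA] = RA_tot·[ET1] / (K_d(1 + I/K_ia) + [ET1])
    [ET1-RB] = RB_tot·[ET1] / (K_d(1 + I/K_ib) + [ET1])

Free ET-1 given total ET-1 is the physical root of the resulting
third-order polynomial. It is solved by safeguarded bracketed root-finding
(Brent) on `[0, ET1_tot]` rather than the analytic cubic formula: the
bracket guarantees the physical root and avoids catastrophic cancellation
when one affinity is extreme (a "perfectly selective" drug is encoded as
`K_i = 1e20` by convention, or `math.inf`, which drops the term
analytically). Solver tolerances are effectively machine precision
(`xtol = 1e-24`, `rtol ≈ 4·eps`), so the mass balance
`[ET1] + [ET1-RA] + [ET1-RB] = [ET1]tot` holds to better than 1e-9
relative across the ~1e-3 … 1e7 pmol/L range the sweeps cover. Receptor
fractions of exactly 0 or 1 degenerate cleanly to a single-receptor
system.

### Parameters

All concentrations are pmol/L (`[ECE]` quoted in nmol/L), volumes in L,
times in minutes. Calibrated defaults:

| symbol | meaning | default | units |
|---|---|---|---|
| BigET(0) | baseline Big ET-1 | 0.93 | pmol/L |
| [ET1]p(0) | baseline free plasma ET-1 | 3.2 | pmol/L |
| kcat/Km | ECE catalytic efficiency | 2.64e-4 | L/min/pmol |
| K_d | ET-1 dissociation constant (ET_A = ET_B) | 400 | pmol/L |
| V_p, V_t | central / tissue volume | 81.6, 2.64 | L |
| K_pt, K_tp | distribution rates | 0.87, 0.98 | /min |
| K_int | complex internalization rate | 0.0095 | /min |
| R_tot,p | plasma receptor pool | 460 | pmol/L |
| R_tot,t | tissue receptor pool | 7,738 | pmol/L |
| f_B,t / f_B,c | ET_B receptor fraction, tissue / plasma | 0.65 / 0.8 | — |
| [ECE] | enzyme concentration | derived (58.81) | nmol/L |

`K_int` is interpreted as a first-order rate constant (/min) applied to
the complex concentrations — the only reading under which the balance
equations are dimensionally consistent.

### Baseline resolution — one derived member

The drug-free steady state is anchored at `[ET1]p(0) = 3.2` pmol/L. The
plasma balance then fixes the free tissue concentration,

    [ET1]t(0) = (Kpt·Vp·[ET1]p0 + Kint·Vp·R_tot,p·[ET1]p0/(K_d+[ET1]p0))
                / (Ktp·Vt)  = 88.90 pmol/L,

within 0.7% of the quoted 88.3 (the quoted parameters are rounded). This
quantity is the *free* tissue concentration; the corresponding total
(free + bound) is ≈1,496 pmol/L.

The tissue balance links `[ECE]` (through `Prod_ET1`) and `R_tot,t`:
specifying both generally over-determines the steady state, so a
`ModelParameters` instance specifies exactly one and the other is derived.
The default set keeps the calibrated `R_tot,t = 7,738` pmol/L and derives
a baseline `[ECE] ≈ 58.81` nmol/L. Study simulations in the calibration
stage instead specify the study's `[ECE]` (162.6, 98 or 27 nmol/L) and
derive `R_tot,t`, which is how the calibration itself treats the tissue
pool ("calculated from steady-state constraints"). Either way the initial
condition is an exact fixed point: integrating 1,000 min drug-free moves
no state by more than 0.1% (in practice ~1e-13).

Note the three study-specific `[ECE]` values and `R_tot,t = 7,738` are not
mutually consistent (they imply tissue pools of 3,217 / 13,308 / 22,489
pmol/L); the package surfaces this by refusing over-determined parameter
sets rather than silently drifting off the quoted baseline.

## Simulation

`simulate()` integrates the system with LSODA (rtol 1e-8, atol 1e-10),
restarting at every protocol breakpoint because piecewise-constant
infusions make the right-hand side discontinuous. Two bookkeeping states
(cumulative ET-1 input and cumulative internalized amount) let tests close
the mass balance over any interval to integrator tolerance.

*Tracer mode.* The radiolabeled-bolus design had an unknown, tiny dose; it
is modeled as a 5-min infusion of 0.1% of the baseline plasma ET-1 pool
and the output is reported baseline-subtracted and peak-normalized, which
is exactly how such relative data are fit.

*Antagonist exposure.* The source studies report antagonist infusion
rates, not concentrations, and no antagonist pharmacokinetics. Default:
a one-compartment infusion model (volume = V_p, elimination half-life
60 min — a deliberate, prominent assumption, configurable per protocol); a
zero-order "step exposure" mode holds a fixed concentration instead.

*Pharmacodynamic delay.* Optionally, the tissue compartment sees an
effect-compartment concentration `dCe/dt = ke0·(I_plasma − Ce)` instead of
the plasma concentration (`ke0` default 0.05/min). This reproduces the
slower early ET-1 rise seen under ET_B blockade.

## Steady states under constant antagonist exposure

Two operating points are provided, and the distinction matters:

1. **Asymptotic (algebraic) steady state** — nested bracketed root-finds
   on the two free concentrations; the outer tissue balance is monotone
   once the plasma balance is eliminated, so the solve is deterministic
   and globally convergent, and it is verified against 1,000-min
   integrations (0.1%).
2. **Finite-horizon quasi-steady state** — integrate 24 h of constant
   exposure from the drug-free baseline.

At the true asymptote, summing the ET-1 balances shows that total
clearance must equal production, i.e. `Kint·(Vt·cplx_t + Vp·cplx_p)` is
*invariant in the drug concentration*: competitive blockade is always
eventually surmounted by ET-1 accumulation, and the antagonized complexes
recover. The published rise-then-fall of the spared complex at high
concentrations of a finitely selective drug is therefore a finite-horizon
phenomenon — the surmounting timescale at high `I` grows without bound
(years and beyond), far outside any physiological regime. Accordingly,
perfectly selective sweeps default to the asymptote (their reported maxima
are indistinguishable from the 24-h values), while finite-selectivity
sweeps default to the 24-h quasi-steady horizon, where the
characteristic non-monotone behavior and deep suppression at equal
affinities appear. `SweepSpec.horizon_min` overrides either choice.

## Selectivity analysis

Concentration grids are log-spaced at 25 points per decade: 0.001–1,000 ×
K_ia for the perfectly selective ET_A antagonist (151 points) and
0.001–100,000 × K_ib for the ET_B case (201 points); selectivity surfaces
span K_ib/K_ia from 1e-4 to 1e4. Reported quantities are percent changes
from the drug-free baseline of both complexes and free ET-1 in both
compartments; summaries report the maximum spared-complex rise, the
concentration multiple giving 50% suppression of the targeted complex, and
the (log-interpolated) multiple at which the spared complex turns
negative, flagged as not reached when beyond the grid.

With the calibrated parameters the package obtains, at the asymptote: a
perfectly selective ET_A antagonist raises plasma [ET1-ET_B] by up to
67.5% and tissue by 49.5%; a perfectly selective ET_B antagonist raises
plasma [ET1-ET_A] by 380% and tissue by 187% over its grid. The plasma
half-suppression point sits at 1.6 × K_ia (ET_A case) versus 3.7 × K_ib
(ET_B case) — the larger ET-1 rise under ET_B blockade pushes its
suppression curve further right. At `f_B = 0.5` in both compartments the
two antagonists become exactly symmetric; at `f_B = 0.999` ET_A blockade
leaves [ET1-ET_B] essentially unchanged while ET_B blockade produces a
very large [ET1-ET_A] rise — bounded, however, by the algebraic cap
`(K_d + x0)/x0` on any complex's fold-rise (≈126 in plasma at baseline
free ET-1 of 3.2 pmol/L), since a complex can never exceed its receptor
pool. Drug presets (bosentan, ambrisentan, atrasentan, sitaxentan,
zibotentan) ship as order-of-magnitude selectivity placeholders meant to
be overridden, not as a reproduction surface.

## Calibration (parameter estimation)

Three study designs are fit simultaneously — tracer bolus (relative mode),
stepped ET-1 infusion, stepped Big ET-1 infusion — sharing all
physiological parameters, with `[ECE]` free per study and the tissue pool
derived per study from the steady-state constraint. The objective is the
plain (unweighted) sum of squared residuals between model-predicted and
observed plasma ET-1 at the studies' actual sampling times; relative-mode
predictions are normalized identically to the data.

Choices that matter:

* all parameters are optimized on the log scale (magnitudes span
  1e-3…1e5);
* the default optimizer is bound-constrained trust-region least squares
  on the residual vector; a scalar L-BFGS-B path is available;
* the finite-difference step is 1e-4 on the log scale — steps near the
  default ~1e-8 fall below ODE-solver noise and stall any optimizer;
* multistart (seeded log-uniform perturbations of the initial point,
  spread ×5) guards against local minima; the best final SSE wins. On
  noise-free synthetic data, 5 starts from twice the true values recover
  every parameter to ~1e-6%.

Approximate relative standard errors use the Gauss-Newton covariance
`s²(JᵀJ)⁻¹` on the log scale, so the standard deviation of `log θ` is
directly the relative error. These are curvature-based approximations:
with the tracer study alone and the full parameter set free, the RSEs of
the plasma receptor pool and `[ECE]` explode (≫100%), reflecting that
relative tracer data carry shape information only — the reason the three
studies must be fit together.

**Identifiability under noise.** The printed sampling schedules contain
few points (4–6 per absolute study). At 10% proportional measurement
noise the joint fit is weakly identified: several directions in parameter
space trade off against each other with almost no residual cost, and
recovered parameters scatter far beyond 20% for most seeds (only `K_int`
remains well determined). The calibration's small quoted uncertainties
are consistent with fitting smooth digitized mean curves, i.e. an
effectively noise-free regime — not with per-sample noise at assay-level
CV. The noisy-recovery test documents this behavior rather than hiding
it.

## Synthetic data

The generator emulates the calibration designs at their printed sampling
times with mean-zero proportional Gaussian noise (default CV 10%, typical
immunoassay precision) plus an optional additive term, truncated at zero.
Replicate bundles derive per-replicate seeds deterministically from a
master seed (`numpy` `SeedSequence.spawn`). What it does *not* emulate:
inter-subject variability (the sources report group means), assay
cross-reactivity (e.g. Big ET-1 interference), receptor up/down-regulation
and circadian or posture effects — so passing recovery tests demonstrate
estimator correctness under the stated error model, not robustness to
those real-data features.

## Global sensitivity

Saltelli sampling (scrambled Sobol sequence in 2k dimensions, split into
A/B plus k column-swapped hybrids; N·(k+2) evaluations) with the Saltelli
first-order and Jansen total-order estimators and row-bootstrap confidence
intervals. The estimators reproduce the closed-form indices of
`Y = X1 + 2·X2` (0.2/0.8) and `Y = X1·X2` (3/7, 4/7) within 0.05 at
N = 1024 and agree with an independent reference implementation. Default
parameter ranges are uniform ±3 calibration RSEs around the calibrated
values (fractions capped at 1); the sampled output functional is the
maximum plasma [ET1-ET_B] rise under perfect ET_A antagonism. Its variance
is dominated by the tissue ET_B fraction (total-order index ≈0.99 at
N = 64) — the selectivity conclusions hinge almost entirely on `f_B`.

## Problem sizes and runtimes

Defaults are sized for interactive use on one core: sweeps of 151/201
steady-state solves run in ~1 s; the Sobol ranking uses N = 64 (640 model
evaluations, ~2 s) and the analytic checks N = 1024; the noise-free
recovery study is a single 5-start fit (~40 s); the noisy robustness study
uses 20 replicate datasets with single-start fits (~4 min). All are
configurable upward.

## Known limitations

Receptor pools are constant (no regulation by antagonism); one shared
K_d; two compartments with a single lumped "tissue"; constant endogenous
production; no inter-individual variability or sex differences; antagonist
pharmacokinetics are an assumption, not a fit; drug selectivity presets
are placeholders. The finite-horizon quasi-steady convention for finite
selectivity is a modeling choice documented above, not a property of the
asymptotic system.
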