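# etkinetics

Mechanistic modeling of endothelin-1 (ET-1) kinetics and competitive
ET_A/ET_B receptor antagonism.

ET-1 is a potent vasoactive peptide implicated in pulmonary arterial
hypertension and diabetic kidney disease. Selective ET_A antagonists are
therapeutically attractive but cause fluid retention, possibly through
changed ET-1 binding to the unantagonized ET_B receptor. The catch is that
ET-1 is *cleared* mainly by receptor binding and internalization
(predominantly ET_B), so blocking either receptor also blocks clearance:
free ET-1 accumulates and signalling through the other receptor can rise.
Quantifying that trade-off as a function of drug concentration and
selectivity is what this package is for. Its users are pharmacometricians
and quantitative systems-pharmacology modelers working on the endothelin
axis.

## The model

Two compartments (central/plasma and tissue), with Big ET-1 converted to
ET-1 by endothelin-converting enzyme (ECE) in the tissue:

    dBigET/dt         = Prod_BigET − (kcat/Km)·BigET·[ECE]
    Vt·d[ET1]tot,t/dt = Prod_ET1 − Ktp·Vt·[ET1]t + Kpt·Vp·[ET1]p
                        − Kint·Vt·([ET1-RA]t + [ET1-RB]t)
    Vp·d[ET1]tot,p/dt = Ktp·Vt·[ET1]t − Kpt·Vp·[ET1]p
                        − Kint·Vp·([ET1-RA]p + [ET1-RB]p)

Binding is in quasi-equilibrium with a shared K_d; under a competitive
antagonist at concentration I the complexes are

    [ET1-RA] = RA_tot·[ET1] / (K_d(1 + I/K_ia) + [ET1]),

and free [ET1] given total ET-1 is the physical root of the resulting
cubic, solved by bracketed root-finding (robust for "perfectly selective"
drugs with an off-target K_i of 1e20 or infinity). On top of the core
model the package provides the calibration study protocols, simultaneous
multi-study least-squares estimation with study-specific [ECE], a
synthetic-data generator, Sobol global sensitivity analysis, and the
antagonist concentration × selectivity sweeps. See `docs/methods.md` for
assumptions, parameters and numerical choices.

## Worked example

```python
from etkinetics import ModelParameters, resolve_baseline
from etkinetics.selectivity import SweepSpec, run_sweep, summarize_sweep

params = ModelParameters()            # calibrated defaults
b = resolve_baseline(params)
print(f"baseline: plasma free ET-1 = {b.et1_p_free:.1f} pmol/L, "
      f"tissue free ET-1 = {b.et1_t_free:.1f} pmol/L, ECE = {b.ece_nmol:.1f} nmol/L")

for mode in ("eta_perfect", "etb_perfect"):
    summary = summarize_sweep(run_sweep(SweepSpec(mode=mode), params))
    print(summary.round(2).to_string(index=False))
```

prints

```
baseline: plasma free ET-1 = 3.2 pmol/L, tissue free ET-1 = 88.9 pmol/L, ECE = 58.8 nmol/L
      label  selectivity compartment  max_spared_rise_pct  i50_multiple  spared_zero_cross_multiple
perfect_ETA          inf      plasma                67.54          1.60                         NaN
perfect_ETA          inf      tissue                49.53          1.94                         NaN
      label  selectivity compartment  max_spared_rise_pct  i50_multiple  spared_zero_cross_multiple
perfect_ETB          0.0      plasma               379.68          3.72                         NaN
perfect_ETB          0.0      tissue               186.63          4.54                         NaN
```

Reading this: the drug-free steady state sits at 3.2 pmol/L free plasma
ET-1 and 88.9 pmol/L free tissue ET-1. Sweeping a perfectly selective
ET_A antagonist from 0.001× to 1,000× its affinity raises the *spared*
complex [ET1-ET_B] by at most 67.5% in plasma (49.5% in tissue), and the
concentration needed to halve [ET1-ET_A] is shifted to 1.6× K_ia by the
compensatory ET-1 rise. A perfectly selective ET_B antagonist — blocking
the dominant clearance route — drives a much larger [ET1-ET_A] rise
(380% plasma, 187% tissue) and a larger suppression shift (3.7× K_ib).
The spared complex never falls below baseline for perfectly selective
drugs (`NaN` = crossing not reached); for finitely selective drugs it
rises then falls, crossing zero at a concentration that grows with
selectivity (`SweepSpec(mode="grid", selectivities=...)`).

A CLI mirrors the analysis stages:

```bash
etkinetics protocols list
etkinetics simulate --protocol stepped_et1 --out sim.csv
etkinetics generate --seed 42 --cv 0.1 --out data.csv
etkinetics fit --data data.csv --out fit.json
etkinetics sobol --n 128 --out sobol.csv
etkinetics sweep --mode etb_perfect --summary --out sweep.csv
```

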