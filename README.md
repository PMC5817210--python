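# qtgp

Virtual-trial simulation and symbolic-regression analysis of drug-induced
QTc prolongation.

Drug-triggered prolongation of the heart-rate-corrected QT interval (QTc)
is the standard surrogate for Torsade-de-Pointes risk in drug development.
The canonical case is terfenadine: its CYP3A4-mediated metabolism makes it
a victim of drug–drug interactions, so co-administration with metabolic
inhibitors (ketoconazole, erythromycin, fluoxetine, …) raises its exposure
and its block of cardiac ion channels.  This package rebuilds, as a tested
and reusable pipeline, an analysis of which physiological and drug-related
covariates drive the change in QTc (dQTc) across simulated clinical trials
of terfenadine given alone or with seven interacting drugs:

* a **synthetic virtual-trial generator** calibrated to the published
  per-variable summary of the original 10,360-record / 63-patient data set
  (the original tables came from proprietary simulators and were never
  deposited);
* the **preprocessing** chain: ±5% noise replicas, linear scaling to
  ⟨0.1; 0.9⟩, and leave-one-inhibitor-out 8-fold cross-validation, in
  which each fold must predict a drug combination absent from training;
* **feature ranking** by performance-weighted permutation importance with
  the 5%-of-total-sum drop cut-off;
* a **genetic-programming engine** for symbolic regression with
  age-fitness-complexity Pareto selection, size limits, periodic elite
  cross-validation and derivative-free constant refitting;
* the **white-box dQTc equation** produced by that kind of search, with
  its response-surface and channel-comparison analyses.

## The model

The white-box model maps eight covariates — body surface area X6 (m²),
plasma K⁺ (X8), Na⁺ (X9) and Ca²⁺ (X10) concentrations (mM), and the
fractional inhibition of the IKr (X11), IKs (X12), INa (X13) and ICaL
(X14) currents — to dQTc in ms:

    dQTc = sin(X14)·X9 + C2·X13·X14·X8·sin(X6) + X14·X8
         + sin(C1·X12·X14²) + X11·X14
         + sin(e^(C4·X14)·X9 + X11·e^(e^X11))
         + C3·X11 + 2·sin²(X10)

with C1 = −14.09525, C2 = 7.706551, C3 = 46.69071192, C4 = 4.587024.
The printed source of this equation is typographically ambiguous (lost
parentheses, unstated input scale); `qtgp.qt_model` packages the reading
above as canonical and keeps all 48 alternative readings as scoreable
candidates — see `docs/methods.md` for how the canonical reading was
selected and what it reproduces.

Model fit is reported as NRMSE = RMSE / (Xmax − Xmin) × 100 (Xmax, Xmin
the observed dQTc extremes) and the coefficient of determination R².

## Worked example

The numbered scripts under `analysis/` run the whole chain; each is a thin
driver over the library.  For instance, the channel comparison
(`python analysis/06_channel_comparison.py`) sweeps both channel
inhibitions over 0…1 with every other input at its observed median and
prints:

    ICaL-sweep vs IKr-sweep OLS: slope 2.6065, intercept 9.7235 ms, R^2 0.9947
    reading: near-linear relation; equal fractional ICaL inhibition changes
    dQTc about 2.6x as much as IKr inhibition

i.e. the two dominant channel effects are near-linearly related, with the
ICaL effect roughly twice the IKr effect per unit inhibition — the two act
in opposite physiological directions, so this ratio matters for balancing
multichannel block.  A desk-scale end-to-end run of generation → ranking →
evolution → grouped cross-validation (`python analysis/04_fit_symbolic_model.py`,
3,000 mechanistic records, 30k-evaluation budget) prints per-fold held-out
scores and

    pooled NRMSE 2.867%, mean-over-folds 3.083%, noised-set 2.975%

showing the engine recovers a compact model that extrapolates to held-out
drug combinations with a few-percent normalized error.  The full pipeline
is also available as a CLI (`qtgp run-all --seed 7 --outdir out/`), with
one subcommand per stage (`generate`, `preprocess`, `rank`, `evolve`,
`respond`, `compare-channels`, `evaluate`).

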