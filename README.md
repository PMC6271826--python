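# ramanpls

Quantification of carbamazepine polymorph mixtures in tablets from Raman
spectra, by interval partial least squares (iPLS).

## The problem

Carbamazepine (CBZ), a widely used anticonvulsant, crystallizes in several
polymorphic forms with different dissolution rates — notably form I, form
III (the marketed form) and a dihydrate (CBZ DH) into which form III can
convert under humid storage. Because CBZ absorption is dissolution-limited,
the polymorphic composition of a finished tablet is a quality attribute,
and it must be measured *in the presence of excipients*, which dominate the
tablet by mass (here 250 mg of excipients per 50 mg of CBZ, i.e. a 16.67%
API load). Raman spectroscopy suits this task: aromatic APIs scatter
strongly while cellulose-type excipients are weak Raman scatterers, and
tablets need no preparation.

This package implements the complete chemometric workflow for that
measurement as a tested, reusable library plus CLI:

* a **synthetic spectrum generator** emulating the 15-tablet ternary
  mixture design (10 calibration + 5 validation tablets, each 300 mg with
  a nominal 50 mg of CBZ split between the three forms) and the replicate
  acquisition protocol (10 spectra per tablet, 52–1708 cm⁻¹);
* **preprocessing**: replicate averaging, area normalization, first
  derivative (Savitzky–Golay);
* **NIPALS PLS2 regression** with leave-one-out cross-validation and a
  parsimony rule for the number of latent variables;
* **iPLS interval selection**: an equidistant partition of the wavenumber
  axis and a greedy forward search for the interval combination minimizing
  the cross-validated error (with an exhaustive-search oracle for small
  partitions);
* **error reporting** on both concentration bases (per total CBZ mass and
  per total tablet mass).

## The model

Tablet spectra are modelled as linear mixtures of pure-component spectra
in tablet-mass fractions. After averaging the replicates of tablet *i*,
normalizing to unit area and differentiating, the feature row
**x**ᵢ enters a PLS2 regression against the responses
**y**ᵢ = (yᴵ, yᴵᴵᴵ, yᴰᴴ), each the polymorph's percentage of the tablet's
total CBZ mass. Errors are root-mean-square errors,

    RMSE = sqrt( Σᵢ (yᵢ − ŷᵢ)² / n ),

evaluated on the calibration fits (RMSEC), the leave-one-out held-out
predictions (RMSECV) and the five validation tablets (RMSEV). An error on
the CBZ-mass basis converts to the whole-tablet basis by multiplying with
the CBZ tablet fraction (50/300): a 9.49% CBZ-basis error is a 1.58%
tablet-basis error.

## Worked example

```sh
$ ramanpls generate --seed 1 --out-dir demo --noise-preset paper-like
wrote 150 spectra to demo (seed 1)

$ ramanpls calibrate --data-dir demo
selected intervals [52-132, 872-952, 1036-1116, 1364-1444] cm^-1; 3 latent variables; RMSECV 1.914% of CBZ mass

$ ramanpls validate --data-dir demo
Parameter            CBZ_I         CBZ_III          CBZ_DH
RMSEC          0.76 (0.13)     1.01 (0.17)     0.76 (0.13)
RMSECV         2.01 (0.34)     2.47 (0.41)     1.41 (0.23)
RMSEV          2.05 (0.34)     1.49 (0.25)     0.69 (0.12)
R2                   0.998           0.999           0.999
(n_cal=10, n_val=5, CBZ fraction of tablet=16.71%)
```

Reading the output: the model was calibrated on the 10 calibration
tablets only; the greedy search kept four of the 20 candidate wavenumber
intervals and three latent variables. Each table cell is an error in
% wt/wt on the CBZ-mass basis with the tablet-mass basis in brackets —
e.g. the CBZ I validation error of 2.05% of the tablet's carbamazepine
corresponds to 0.34% of the whole tablet. R² pools the calibration and
validation tablets. The same run is available from Python via
`ramanpls.pipeline.run_full(RunConfig(seed=1, noise="paper_like"), "demo")`.

## Layout

```
src/ramanpls/
  design.py      # 15-tablet ternary mixture design, mass fractions
  spectra.py     # Spectrum container, default 52-1708 cm^-1 grid
  synthetic.py   # peak library + replicate spectrum simulator
  preprocess.py  # average -> area-normalize -> first derivative -> intervals
  pls.py         # NIPALS PLS2, explained variance, LV parsimony rule
  intervals.py   # axis partition, greedy/exhaustive iPLS search
  metrics.py     # RMSE/R^2, LOO driver, basis conversion, error report
  pipeline.py    # config-driven generate/calibrate/validate stages
  cli.py, io.py  # command line and CSV/JCAMP/JSON persistence
```

See `docs/methods.md` for the modelling assumptions, the synthetic
generator's scope, and known limitations (including the response
nonlinearity floor of the noiseless design).
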