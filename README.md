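# nirstab

Chemometric quality-control toolkit for near-infrared (NIR) spectra of
smoke condensate collected on Cambridge filter pads. It answers two
questions a tobacco QC lab asks of a stream of production batches:

1. **Product stability** — how far does each product batch sit from the
   brand's verified standard samples, and how does that distance evolve
   along the production timeline?
2. **Instrument-configuration equivalence** — after swapping the sample
   container cup (here: a classical Bruker cup vs a shallower self-made
   cup), do paired measurements of the same sample stay close enough that
   the stability analysis is unaffected?

It is a library first (`import nirstab`), with an `examples/` directory of
narrative scripts and a thin `nirstab` CLI for shell use.

## The method

Absorbance spectra on a shared uniform wavenumber grid (the instrument
default is 4000–12496 cm⁻¹ at 8 cm⁻¹ steps) are preprocessed in three
steps: Savitzky–Golay smoothing, multiplicative scatter correction (MSC:
per-spectrum OLS regression on a reference spectrum, then the inversion
`(x − a) / b`), and a Savitzky–Golay first derivative with a second-order
polynomial.

Stability is the (squared) Mahalanobis distance of a preprocessed product
spectrum `x` to the brand's standard-sample distribution,

```
D = (x − μ) C⁻¹ (x − μ)ᵀ
```

with `μ` and `C` the mean and covariance of the preprocessed standard
spectra. With tens of standards and ~1000 wavenumber points `C` is
singular, so the default model evaluates `D` in the PCA subspace retaining
99 % of the standards' variance (`D = Σⱼ (vⱼ·(x−μ))²/λⱼ`); Ledoit–Wolf
shrinkage and the classical full-rank covariance are alternatives.

Cup equivalence compares two distance populations under that same metric:
the paired distance `(x_old − x_new) C⁻¹ (x_old − x_new)ᵀ` between the two
cup measurements of one sample, and the sample-to-standard distances. A
separation ratio (median sample D / median paired D) far above 1 means the
cup change is negligible relative to ordinary product variability; a
Wilcoxon rank-sum comparison is attached as a convenience statistic.

Because real smoking-machine campaigns are largely confidential, the
package ships a first-class synthetic study generator
(`nirstab.simulate`): two brands with distinct Gaussian-band signatures,
batch/pad random effects, empty-pad background, multiplicative scatter,
detector noise and a small systematic cup shift — enough structure to
exercise and validate every stage end to end.

## Worked example

```python
import nirstab as ns

study = ns.simulate_study(ns.scaled_study_config(seed=1))
report = ns.analyze_study(study, reference_brand="TT")
s = report.summary
print(s["median_paired"], s["median_sample"], s["median_inter_brand"])
```

Running `python examples/04_cup_equivalence.py` prints:

```
pairs: 160, product samples: 160
median paired-cup D:        0.110  (range 0.024 .. 1.37)
median sample-to-standard D: 18.9  (range 2.8 .. 80.0)
separation ratio (sample/paired medians): 172.7
rank-sum p (sample vs paired location):   5.72e-54
```

Reading: the two cup configurations differ by a median D of 0.11 while
ordinary product batches sit a median D of 18.9 from the standard — the
cup change perturbs the measurement ~170× less than routine product
variation, so the cups are interchangeable for stability monitoring. The
other brand ("AA") scores a median D of ≈ 591 against the TT reference
(`examples/03_stability_timeline.py`), showing the scale at which the
metric flags a genuinely different product.

## Command line

```sh
nirstab simulate --seed 1 --out sim.csv
nirstab fit-reference --standards sim.csv --brand TT --out model.json
nirstab score --model model.json --products sim.csv --out stability.csv
nirstab equivalence --model model.json --spectra sim.csv --out equiv.json
nirstab run --seed 1 --out report/        # end-to-end with a run manifest
```

Exit codes: 0 success, 2 config error, 3 data validation error,
4 numerical failure.

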