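# oligocea

A partitioned-survival cost-effectiveness model of stereotactic ablative
radiotherapy (SABR) for oligometastatic cancer, written for health-economics
analysts who want the whole pipeline — base case, tornado, threshold search
and probabilistic sensitivity analysis — as tested, scriptable Python rather
than a proprietary decision-tree file.

The SABR-COMET randomized trial showed that adding SABR to standard care
(SC) extends overall and progression-free survival in patients with 1–5
metastases. This package asks the follow-on question: *is it worth the
money?* It models a cohort moving through three states read directly off the
survival curves each month,

```
OMD  (oligometastatic, progression-free)  = PFS(t)
PMD  (polymetastatic, progressed)         = OS(t) − PFS(t)
dead                                      = 1 − OS(t)
```

accrues discounted (3%/year) costs and quality-adjusted life years (QALYs)
per monthly cycle with mid-cycle correction, and compares the strategies by
incremental cost-effectiveness ratio (ICER = ΔC/ΔE) and net monetary benefit
(NMB = E·λ − C) at a willingness-to-pay of λ = $100,000/QALY. The bundled
input set carries the published US-setting model inputs (annual OS/PFS
anchors per arm, annual state costs, one-time SABR/salvage/adverse-event
items, an end-of-life lump sum, and utilities 0.82/0.59); your own inputs go
in a YAML file with the same structure. See `docs/methods.md` for the model
in full.

## Worked example

```python
import oligocea as oc

inputs = oc.reference_inputs()               # bundled published input set
results = oc.run_model(inputs)               # both arms, 72 months
cea = oc.compare(results["SABR"], results["SC"], inputs.settings.wtp)
threshold = oc.threshold_search(inputs)
```

which prints, formatted:

```
SABR: cost $298,186  QALY 2.558
SC:   cost $292,724  QALY 1.715
incremental cost $5,463, incremental effect 0.843 QALY
ICER $6,481/QALY; incremental NMB $78,823 at WTP $100,000/QALY
SABR remains cost-effective up to a unit cost of $81,064 (6.9x base)
```

Read: over the six trial years SABR adds about 0.84 discounted QALYs for
about $5,500 extra — roughly $6,500 per QALY, one-fifteenth of the usual US
willingness-to-pay — because the extra time SABR buys is mostly spent
progression-free, where systemic-therapy costs are half those of progressed
disease. The last line is the threshold analysis: SABR delivery could cost
almost seven times its current $11,700 before ceasing to be cost-effective.

The same analyses are available from the shell, each writing CSV/JSON
reports plus a reproducibility manifest:

```
oligocea base-case --out-dir out/base
oligocea dsa --out-dir out/dsa
oligocea threshold --out-dir out/threshold
oligocea psa --n 10000 --seed 1 --out-dir out/psa
oligocea base-case --horizon-months 192 --reference-curve ref.csv --out-dir out/lt
```

For 16-year horizons the overall-survival curves are spliced onto a registry
reference curve (`--reference-curve`, two-column CSV) and PFS is extended
proportionally; without one, a clearly-labelled synthetic stand-in curve is
used so the machinery stays testable offline.

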