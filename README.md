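# labqc

Quality-control analytics for clinical laboratory networks: internal
quality control (IQC) with Westgard multirules, consensus-based
interlaboratory comparison, multirule screening of external quality
assessment (EQA) data, top-down measurement uncertainty, and ratio-type
quality indicators — plus a synthetic multi-laboratory data generator so
every engine can be exercised with known ground truth.

## Who it is for

Regional laboratory networks (a central laboratory plus district/branch
laboratories) that run the same control materials on many instruments and
need to answer, reproducibly: *is each analytical run in control, is each
laboratory consistent with its peers, do acceptable EQA results hide a
latent systematic or random error, and how uncertain is a reported patient
result?*

## What it computes

**IQC / Levey-Jennings.** Control results are standardized against fixed
targets, `z_i = (x_i − μ_t)/σ_t`, and screened with a configurable Westgard
rule set (default `1_2s` warn; `1_3s`, `2_2s`, `R_4s`, `4_1s`, `10_x`
reject). Monthly summaries report n, mean, sample SD, CV and bias per
analyte/level/lot, with out-of-control flags and CV-requirement verdicts.

**Interlaboratory comparison.** Consensus groups (affiliated network, peer
= same instrument/reagent/method, method = same methodology code) pool raw
member observations. A laboratory is scored by the standard deviation index
and CV ratio,

    SDI = (x̄_lab − x̄_group) / s_group        CVR = CV_lab / CV_group

with tiered verdicts (defaults: |SDI| ≤ 1.25 acceptable, ≤ 2.0 monitor;
CVR ≤ 1.0 acceptable, ≤ 1.5 monitor).

**EQA multirule screen.** For a date-ordered series of *acceptable* EQA
events, using the percentage deviation `pd = 100·(x − x̄_g)/x̄_g` and the
SDI: `1_TEa`, `1_75%TEa`, all-results-on-one-side (potential systematic
error), 2-of-3 consecutive |SDI| > 2 on one side, and an SDI range rule
(potential random error). Quality indicators (IQC implementation rate, CV
failure rate, interlaboratory-comparison rate for items without an EQA
program, EQA coverage and unacceptable rates) are percentages with exact
numerator/denominator bookkeeping, and indicator proportions can be
compared across periods with Pearson/Yates chi-square or Fisher exact
tests.

**Measurement uncertainty (top-down).** From IQC and EQA summaries:

    u_Rw   = long-term IQC CV (pooled over lots)
    u_bias = sqrt( RMS(EQA % deviations)² + u_cref² )
    u_c    = sqrt( u_Rw² + u_bias² )          U = k · u_c   (k = 2 default)

plus the two clinical applications: a coverage interval
`x · (1 ∓ U/100)` around a result near a decision limit, and the minimum
significant difference between serial results,
`MSD = z·√2·(u_c/100)·x` (z = 1.96).

## Worked example

Retinol binding protein (RBP), two IQC levels with means 25 and 46 mg/L
and a six-result EQA deviation history:

```python
from labqc import rbp_example, mu_report, result_interval, is_significant

ex = rbp_example()
rep = mu_report(ex.mu_input)
for lvl in rep.levels:
    print(lvl.level, round(lvl.u_c, 2), round(lvl.u_expanded, 2), lvl.goal_met)
print(result_interval(28.0, rep.levels[0].u_expanded).rounded)
print(is_significant(71.0, 68.0, rep.levels[1].u_c))
```

prints

```
1 7.59 15.18 True
2 4.44 8.88 True
(23.75, 32.25)
SerialComparison(earlier=71.0, later=68.0, difference=3.0,
                 threshold=8.738006994688893, significant=False)
```

Read: at level 1 the relative expanded uncertainty is 15.18 %, so a
patient result of 28 mg/L (reference range 25–70 mg/L) carries a 95 %
interval of 23.75–32.25 mg/L — the low end of normal cannot be ruled out.
At level 2 the combined uncertainty is 4.44 %, so two serial results must
differ by more than ≈ 8.74 mg/L before the change is more than analytical
noise; the observed 3 mg/L drop from 71 to 68 mg/L is not significant.

The same report renders as a four-section markdown document
(experimental information, EQA statistics, MU statistics, conclusion) via
`labqc mu estimate --config mu.json --format markdown`.

## Command line

```bash
labqc simulate --seed 7 --outdir data/          # synthetic network (CSV + truth.json)
labqc iqc evaluate --observations data/observations.csv --specs data/specs.csv \
    --month 2024-01 --out summary.json
labqc interlab compare --observations data/observations.csv --lab LAB01 \
    --group peer --month 2024-01 --out compare.json
labqc eqa analyze --eqa data/eqa.csv --out eqa.json
labqc indicators compute --name iqc_implementation_rate --numerator 97 --denominator 100
labqc indicators compare --n1 100 --x1 50 --n2 100 --x2 50 --method chisq_yates
labqc mu estimate --config examples/mu_input.json --format markdown
```

CSV schemas (fixed headers) and YAML/JSON config examples are in
`examples/`.

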