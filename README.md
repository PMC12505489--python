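# ldlkit

Tools for comparing LDL-cholesterol estimating equations on lipid-panel
data: the Friedewald formula, the Martin-Hopkins equation (adjustable-factor
lookup), and the Sampson-NIH equation, plus the clinical-category
concordance machinery used to judge whether switching equations would change
treatment decisions. A synthetic cohort generator with hidden ground truth
makes the whole analysis runnable and testable without any patient data.

## What's inside

| module | contents |
| --- | --- |
| `ldlkit.units` | mmol/L ↔ mg/dL conversion (38.67 for cholesterol, 88.57 for TG), `LipidPanel` |
| `ldlkit.mh_table` | `MhFactorTable` lookup (half-open, lower-inclusive cells) + packaged 180-cell median-factor table; CSV (de)serialization |
| `ldlkit.equations` | `ldl_friedewald`, `ldl_martin_hopkins`, `ldl_sampson`, `compute_all` with validity flags (FF absent at TG ≥ 4.52 mmol/L; MH limit 4.51 or 9.04 with `extended=True`; Sampson limit 9.04; everything excluded above 9.04) |
| `ldlkit.categories` | clinical LDL-C categories (<1.81 … ≥4.90 mmol/L), TG strata, percentage-difference summaries, crosstabs, Cohen's kappa + Landis-Koch labels |
| `ldlkit.agreement` | median/IQR, Wilcoxon signed-rank, Spearman rho, Bland-Altman limits of agreement |
| `ldlkit.cohort` | `SyntheticCohortConfig`, log-normal marginals fit from median/IQR, TG:VLDL-C ratio ramp (5→9 over 100–400 mg/dL TG), artifact injection (repeat visits, age/TG outliers) |
| `ldlkit.pipeline` | CSV reader with reject handling, study filters (age 18–75, earliest visit per patient, TG ≤ 9.04) with a conserving audit, full analysis report writer |

Negative estimates are returned and flagged, never clamped; they classify
into the lowest category. Percentage differences are `100·(a−b)/b`
(relative to the second-named value); the pipeline orients its pairs as
(MH, FF), (Sampson, FF), (MH, Sampson), which yields the characteristic
negative-to-positive gradient across TG strata.

## CLI

```bash
# synthetic cohort (defaults emulate the published cohort marginals)
ldlkit simulate --seed 1 --n 20000 --out cohort.csv

# per-record estimates by all three equations
ldlkit compute cohort.csv --out estimates.csv

# full study: filters -> estimates -> stratified differences, crosstabs,
# kappa, Bland-Altman; writes CSV/JSON tables (+ --plots for PNGs)
ldlkit analyze cohort.csv --out report/

# re-render plots from an existing report directory
ldlkit report report/
```

Useful flags: `--config cfg.yaml` (simulate), `--units mg/dL`,
`--mh-table my_table.csv`, `--extended-mh/--original-mh`.

## Library example

```python
import ldlkit as lk

panel = lk.LipidPanel(total_cholesterol=4.94, hdl_cholesterol=1.32,
                      triglycerides=0.96)          # mmol/L
est = lk.compute_all(panel, extended=True)
print(est.ff.value, est.mh.value, est.sampson.value)
```

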