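# faerspv

Disproportionality and subgroup analysis of spontaneous adverse-event
reports in the FAERS quarterly layout, built around the question of cardiac
adverse events (CAEs) reported for compound inhaled long-acting
bronchodilators (LABA/LAMA duals and ICS/LABA/LAMA triples). It is aimed at
pharmacovigilance analysts and methods researchers who want the whole
screen — ingestion, deduplication, cohort construction, signal statistics
and subgroup summaries — as tested, reusable code rather than a chain of
ad-hoc SQL and spreadsheets.

## What it computes

For each (drug, event) pair the reports are laid out in a 2×2 table against
the whole-database background —

|              | event PT | no event PT |
|--------------|----------|-------------|
| target drug  | a        | b           |
| other drugs  | c        | d           |

with the report as the counting unit, and four estimators are evaluated:

- **ROR** = (a·d)/(b·c), 95% CI `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`
- **PRR** = [a/(a+b)] / [c/(c+d)], 95% CI
  `exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`
- **MHRA χ²** with Yates continuity correction (configurable)
- **BCPNN information component** IC = log₂ of the shrunken
  observed-to-expected ratio (Bate's closed form), with IC025 = IC − 2·√V(IC);
  it stays defined for zero cells and is used alone for pairs with a < 3.

A pair is a **combined signal** only when a ≥ 3, both 95% lower bounds
exceed 1, PRR ≥ 2 and χ² ≥ 4 simultaneously; signal intensity is graded
from IC025 (weak ≤ 1.5 < moderate ≤ 3 < strong).

Around that core the package provides: `$`-delimited FAERS table parsing
with partial-date handling; case-version deduplication (latest
`fda_dt`/`caseversion` per `caseid`); primary-suspect drug-name matching
with per-product market-entry search windows; PT→SOC mapping (a synthetic
MedDRA-style mock ships; a licensed export drops in); time-to-onset binning
and cumulative curves; death-outcome stratification; co-reported-event
ranking; demographic characteristic tables; and a seeded synthetic FAERS
generator with exported ground truth for calibration and recovery studies.

## Worked example

```python
from faerspv import synthetic, pipeline

tables, truth = synthetic.generate(synthetic.paperlike_config(seed=7))
res = pipeline.run_from_frames(tables)
s = res.manifest["stages"]
print(f"reports after dedup: {s['demo_after_dedup']}"
      f"  (removed {s['dedup_removed']} superseded versions)")
print(f"target-drug reports: {s['matched']}   cardiac-event cases: {s['cae_cases']}")
cols = ["product_id", "pt", "a", "ror", "ror_lo95", "prr", "chi2", "ic025", "intensity"]
top = res.screen_df[res.screen_df.combined_signal].sort_values("ror", ascending=False)
print(top.head(5)[cols].round(2).to_string(index=False))
```

prints

```
reports after dedup: 23120  (removed 2271 superseded versions)
target-drug reports: 2973   cardiac-event cases: 774
product_id                               pt  a   ror  ror_lo95  prr   chi2  ic025 intensity
       FUV         Ventricular fibrillation 50 10.15      7.08 9.83 236.21   2.03  moderate
       FUV                Cardiogenic shock 39  8.41      5.67 8.20 155.83   1.80  moderate
       FUV Arteriosclerosis coronary artery 36  8.32      5.53 8.14 142.33   1.76  moderate
        FG              Atrial fibrillation 32  5.79      3.97 5.33 102.41   1.61  moderate
        OT                   Cardiac arrest 47  5.36      3.87 5.16 124.47   1.55  moderate
```

Here the generator injected elevated reporting ratios for exactly these
pairs (e.g. ventricular-fibrillation reports for the triple product FUV at
nine times the background rate); the screen recovers them with
disproportionality estimates close to the planted ratios, and pairs with no
injected dependence stay below the combined threshold.

The same analysis runs from the shell on a directory of FAERS-style tables:

```bash
faerspv synth --seed 7 --out data/        # or real DEMO*/DRUG*/REAC*/... files
faerspv analyze --input data/ --out results/
```

`analyze` writes `signal_screen.csv`, `bcpnn_lowcount.csv`,
`demographic_summary.csv`, `onset.csv`, `death_subset.csv`,
`co_reported.csv`, the PRR heat-map and intensity matrices as JSON, and a
`manifest.json` with row counts and exclusion tallies for every stage.

## Layout

- `src/faerspv/faers_io.py` — table parsing, deduplication, case linking
- `src/faerspv/cohort.py` — drug matching, search windows, PT→SOC, CAE extraction
- `src/faerspv/disproportionality.py` — 2×2 tables, ROR/PRR/χ²/IC, screening
- `src/faerspv/subgroups.py` — onset, demographics, deaths, co-reported events
- `src/faerspv/synthetic.py` — seeded generator with ground truth
- `src/faerspv/pipeline.py`, `cli.py` — orchestration and the `faerspv` CLI
- `docs/methods.md` — models, parameter choices, limitations
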