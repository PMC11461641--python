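# fdgmismatch

Analysis pipeline for the **metabolism–contractility mismatch** phenotype
seen on combined [<sup>18</sup>F]FDG-PET/CMR imaging early after reperfused
myocardial infarction, together with the molecular stages used to explain
it (immune signature scoring of bulk RNA counts, single-nucleus QC,
hashtag demultiplexing, marker-based cell counting, differential
expression and over-representation analysis).

It is written for cardiovascular imaging and molecular groups who quantify
porcine (or clinical) infarcts on the AHA 17-segment polar map and want a
tested, scriptable implementation of the mismatch classifier and its
companion statistics. Because the underlying animal data are not publicly
deposited, the package ships a seeded synthetic-cohort generator that
carries the published group-level structure, so every stage runs
end-to-end out of the box.

## The core classifier

For each of the 17 AHA segments, with LGE transmurality `T_s` and FDG
uptake normalized to the hottest segment `U_s = 100·raw_s/max(raw)`
(both in percent), a segment is *mismatched* when

```
T_s ≥ 75  and  U_s ≥ 75
```

i.e. metabolically active tracer signal co-located with transmural scar.
An animal is assigned to the **Mismatch** group when at least 3 of its 17
day-3 segments are mismatched, otherwise to the **Match** group (the
expected uptake defect over the scar). Mismatch animals go on to show
lower ejection fraction, larger infarcts, and a month-1 uptake *defect* in
the infarct territory — the phenotype the generator encodes and the
statistics module tests (ANOVA + Bonferroni post hoc, OLS regressions,
2^(−ΔΔCt) qPCR fold changes).

## Worked example

```python
from fdgmismatch import CohortConfig, cohort_assign, simulate_cohort

cohort = simulate_cohort(CohortConfig(), seed=1)   # 22 Match / 8 Mismatch phenotype
assignments, prevalence = cohort_assign(cohort.profiles)
print(prevalence)
```

prints

```
{'n_total': 30, 'n_mismatch': 8, 'percent': 26.666666666666668, 'percent_rounded': 27}
```

— the day-3 classifier recovers all 8 configured Mismatch animals of the
30-animal imaging cohort, a 27% prevalence. The same objects drive the
association suite; on this default cohort `03_cohort_statistics.py` prints

```
day-3 EF: Mismatch 32.5 +/- 7.7 vs Match 45.2 +/- 5.2 (p=1.8e-05)
month-1 uptake~contractility: slope 0.578, r 0.750, p 3.9e-93
day-3 MVO~territory uptake: r 0.120, p 0.53 (independent config)
```

— Mismatch EF sits well below Match, month-1 segmental uptake correlates
positively with contractility, and MVO is unrelated to infarct uptake
under the independence config.

## Layout

- `src/fdgmismatch/` — the library: `polarmap` (17-segment model),
  `mismatch` (classifier), `synthetic` (cohort/bulk/nucleus generators),
  `stats` (ANOVA, OLS, ΔΔCt), `immune` (QC, demux, scoring, annotation,
  DE, ORA), `io`/`pipeline`/`cli` (formats, manifested runs, console
  script `fdgmismatch`).
- `analysis/01…05_*.py` — numbered narrative drivers that run the stages
  in order and write their tables under `results/`.
- `tests/` — unit, property and acceptance suites.

A full manifested run: `fdgmismatch run-all --outdir results/run --seed 1`.

## Acceptance script

`scripts/acceptance.py` recomputes the cohort-level quantities from
scratch by running the package: it classifies a deterministically stated
30-animal cohort to obtain the Mismatch prevalence, tabulates the
angiographic TIMI-2 shares of the full 37-animal allocation, and simulates
10,000 animals per group to measure the sample means of day-3 EF (both
groups), day-3 infarct size, month-1 infarct-territory uptake and fasting
glucose. Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
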