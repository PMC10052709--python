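# hepvol

CT hepatic volumetry by slice summation and slice decimation, for imaging
researchers who need to know **how few slices you can trace and still trust the
volume**, and how much manual tracings differ between observers.

Manual CT volumetry segments the liver on every transverse slice and sums the
traced areas:

```
V_full = Σ_i A_i · t          (A_i: slice area, cm²;  t: slice thickness, cm)
```

Tracing every slice is slow. If only every *k*-th slice is traced (slice
interval *k·t*), the volume is extrapolated:

```
V_dec  = ( Σ_{i ∈ subset} A_i · t ) · N / n_used
```

with *N* the total number of liver-bearing slices and *n_used* the slices
actually traced. For a decimation factor *k* there are *k* phase offsets (which
slice is traced first); the phase subsets partition the *N* slices, and the
mean of the *k* phase estimates equals *V_full* exactly whenever *k* divides
*N*. The error of each decimated estimate is

```
pct_diff = |V_dec − V_full| / V_full × 100
```

against the full volume of the *same subject traced by the same observer*.
Interobserver agreement on full volumes is summarised per subject by the
coefficient of variation (CV = SD/mean × 100, sample SD), the greatest percent
difference ((max − min)/mean × 100), and symmetric pairwise differences
(|a − b| / pair mean × 100).

Because clinical canine CT series with tracings are rarely shareable, the
package ships a **phantom generator**: a synthetic cohort of 8 + 8 subjects at
2.5 / 3.75 mm slice thickness, 36–63 liver-bearing slices with smooth unimodal
area profiles, and three simulated observers whose multiplicative tracing
noise is calibrated so the cohort-mean volume CV is 2.5%. Everything downstream
(volumetry, decimation study, interobserver statistics, plots, CLI) runs
identically on real per-slice area tables or NIfTI masks.

## Worked example

```python
import hepvol

spec   = hepvol.PhantomSpec()                # default seeded study conditions
cohort = hepvol.generate_cohort(spec)        # 16 subjects × 3 observers
res    = hepvol.run_study(cohort)            # StudyResults
print(res.summary())
```

prints

```
Cohort: 16 subjects x 3 observers (48 full-volume measurements)
Mean full hepatic volume: 783.2 (+/-312.4) cm^3
Interobserver CV: 2.7 (+/-1.9)%; greatest pct diff: 5.1 (+/-3.5)%
Decimated measurements: 576
Percent difference vs corresponding full volume, by group:
       2.5-5:  1.5 (+/-0.9)% [n=48, 16/observer]
     2.5-7.5:  2.0 (+/-1.8)% [n=72, 24/observer]
      2.5-10:  2.6 (+/-2.1)% [n=96, 32/observer]
      2.5-15:  4.4 (+/-3.5)% [n=144, 48/observer]
    3.75-7.5:  0.6 (+/-0.4)% [n=48, 16/observer]
  3.75-11.25:  2.2 (+/-1.4)% [n=72, 24/observer]
     3.75-15:  3.9 (+/-2.1)% [n=96, 32/observer]
Greatest percent difference by slice interval:
  5 mm: 3.3%  (2.5-5)
  7.5 mm: 7.9%  (2.5-7.5,3.75-7.5)
  10 mm: 7.9%  (2.5-10)
  11.25 mm: 6.2%  (3.75-11.25)
  15 mm: 18.6%  (2.5-15,3.75-15)
Greatest percent difference by number of slices used:
     <10: 18.6%  [n=132]
   10-14: 9.2%  [n=189]
   15-19: 7.1%  [n=135]
   20-24: 4.2%  [n=72]
    >=25: 2.4%  [n=48]
```

Reading it: each "thickness–interval" group (e.g. `2.5-7.5` = 2.5 mm slices,
every third slice) contributes *k* phase-offset estimates per subject per
observer — hence 16/24/32/48 measurements per observer for *k* = 2/3/4/6 and
576 rows overall. Mean error grows with the slice interval, but the *worst*
error is governed by how many slices were actually used: on this cohort every
measurement that used ≥ 20 slices stayed within 5% of its full volume (the
20–24 bin tops out at 4.2%, the ≥25 bin at 2.4%), while fewer than 10 slices
can be off by almost 19%.

`res.measurements`, `res.group_summary()`, `res.interval_summary()`,
`res.bin_summary()`, `res.interobserver_table()` are pandas DataFrames;
`res.plot_by_interval()` / `res.plot_by_slice_count()` draw the scatter with
the 5% acceptability line; `res.to_csvs(outdir)` writes every table.

The same pipeline runs from the shell:

```bash
hepvol generate --out run/ --seed 7          # cohort.csv + spec + manifest
hepvol volumetry --input run/cohort.csv --out run/volumes.csv
hepvol study --cohort run/cohort.csv --out run/study/
```

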