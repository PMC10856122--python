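# endodecay

Biexponential modelling of corneal endothelial cell decay after Descemet
membrane endothelial keratoplasty (DMEK).

Corneal endothelial cells do not regenerate: after an endothelial graft,
the endothelial cell count (ECC, cells/mm²) declines for the rest of the
graft's life, and the graft fails once the density falls below roughly
250–500 cells/mm². Longitudinal specular-microscopy series after
keratoplasty are well described by a two-phase exponential decay

    ECC(t) = a·e^(b·t) + c·e^(d·t),     t in months,  a, c > 0,  b, d < 0,

with a fast component (rate `b`, the surgical trauma of the first ~6
months) and a slow component (rate `d`, chronic attrition). From a fitted
curve one derives the quantities clinicians actually quote:

- **phase half-times** `ln 2 / |b|` and `ln 2 / |d|`;
- **endothelial cell loss** (ECL, %) at a horizon, relative to the
  preoperative donor ECC: `100·(ECC_donor − ECC(t)) / ECC_donor`;
- **threshold-crossing months**: the last whole month at which the
  extrapolated curve still sits at or above a viability threshold.

`endodecay` packages this analysis end to end for biostatisticians and
cornea researchers: a seeded synthetic cohort generator with the
structure of a real DMEK follow-up study (65 eyes, donor ECC ~
truncated-normal N(2518.46, 89.95²) on [2300, 2700], visits at
1/3/6/9/12/18/24 months plus a 14-eye subset at 36 months, a 35/30 split
between DMEK+cataract-surgery and DMEK-only arms), constrained nonlinear
least-squares fitting of mono- and biexponential curves with R²-based
model selection, the derived clinical quantities above, and subgroup
comparison (likelihood-ratio test of each arm's curve against the pooled
curve, per-visit Student's t-tests on per-eye ECL, Pearson chi-squared
on 2×2 complication tables).

## Worked example

The published fit for a 65-eye preloaded-DMEK cohort in Fuchs'
dystrophy is `a = 177.5, b = −0.2298, c = 1580, d = −0.005271` with mean
donor ECC 2518.46 cells/mm². Deriving the clinical quantities from those
coefficients:

```bash
endodecay predict --params "177.5,-0.2298,1580,-0.005271" --baseline 2518.46
```

```json
{
  "ecl_percent_at_months": {
    "120": 66.67101531299804,
    "36": 48.10480977039329,
    "60": 54.27306151279169
  },
  "half_time_early_months": 3.0163062687552014,
  "half_time_late_months": 131.50202628722164,
  "threshold_crossing_months": {
    "250.0": 349,
    "500.0": 218
  }
}
```

Read: the fast phase halves every ~3 months and the slow phase every
131.50 months (~11 years); ECL reaches 48% / 54% / 67% of the donor
count at 3 / 5 / 10 years; the extrapolated curve stays above
500 cells/mm² through month 218 (~18 years) and above 250 cells/mm²
through month 349 (~29 years).

The same derivations are available in Python:

```python
from endodecay import BiexpParams, half_times, ecl_at, time_to_threshold

fit = BiexpParams(a=177.5, b=-0.2298, c=1580.0, d=-0.005271)
half_times(fit)                      # (3.0163..., 131.5020...)
ecl_at(fit, 120, 2518.46)            # 66.67  (% of donor ECC at 10 years)
time_to_threshold(fit, 500)          # 218    (whole months)
```

A full synthetic run — simulate a cohort, fit the pooled mean series
over the first 24 months, extrapolate, and compare the surgical arms —
is one command:

```bash
endodecay run --seed 1 --out demo/
```

which writes `cohort.csv`, fit and summary JSON, a comparison report and
a Markdown summary. With the default generator settings (each arm decays
along the subgroup kinetics reported for real cohorts: late half-times
98.05 vs 250.32 months) the seed-1 run prints a pooled curve
`161.6·exp(−0.2351·t) + 1593.2·exp(−0.004967·t)` (R² = 0.9996), late
half-time 139.55 months, ECL 47%/53%/65% at 3/5/10 years, and crossings
at months 233 and 372; the arm-comparison LRTs reject (h = 1) because
the synthetic measurement noise is far smaller than real between-eye
variability — see `docs/methods.md` for what the generator does and
does not emulate.

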