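# soilgaps

Gap filling, quality control and validation for multi-sensor soil-moisture
networks, built for the kind of long-term dryland monitoring design where a
handful of volumetric water content (VWC) probes sit in contrasting
microsites — tussock grass (*Stipa*), shrub (*Retama*) and open soil with
low, medium or high biocrust cover (BSCl/BSCm/BSCh) — logging sub-daily for
years, with long contiguous outages from dead batteries, maintenance pulls
and wildlife-chewed wires.

It is aimed at ecohydrologists and field-station data managers who need to
turn a raggedy multi-year logger archive into a continuous, provenance-tagged
series, and at anyone who wants to test such a pipeline end to end against
known ground truth.

## The method

**QC.** Readings outside the physical range (negative values, VWC above 1)
are set to missing; bounds are inclusive and configurable. An advisory
peer-consistency report flags probes that decouple from their microsite
neighbours, but never deletes anything by itself.

**Donor selection.** For a target sensor *y* with a gap at time *t*, every
other sensor *x* is scored

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>x</sub>* = %vc<sub>x,y</sub> + 100 ·
R²<sub>x,y</sub> + {100 if microsite<sub>x</sub> = microsite<sub>y</sub>,
else 0}

where %vc is the percent of common valid cases (timestamps where both hold
observed values, relative to the full grid) and R² is the squared Pearson
correlation over those cases. The gap is filled by the highest-scoring donor
observed at *t*, using an ordinary least-squares model *y* ~ *x* fitted once
per pair on all common valid cases, predictions clipped into [0, 1]. Ties
break by overlap, then donor id; imputed values never feed later fills
(single pass) unless you opt into `iterative`.

**Quality column.** Every cell carries provenance: 1 if observed, the donor
model's Pearson correlation coefficient if imputed, missing if unfillable.

**Validation.** Sensor readings are paired with independent reference
measurements (e.g. TDR) from the same calendar day and microsite, and the
sensor value is regressed on the reference: slope β with a 95% Student-t CI
and adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

**Simulator.** A seeded generator produces daily Markov-chain rainfall and
seasonal weather calibrated to a semiarid climate (~349 mm/yr, 15 °C mean),
per-microsite soil moisture from a daily bucket model (plant patches
infiltrate more and dry slower than open biocrust soil), replicate probes
with ±3%-accuracy-level Gaussian noise, Poisson/lognormal block outages
tuned to ~55% missingness, and occasional small negative anomalies — so the
whole pipeline can be checked against known truth.

## Worked example

```python
from soilgaps import (SimConfig, simulate_dataset, flag_anomalies,
                      impute_table, ImputeConfig, make_validation_pairs,
                      paired_regression)

cfg = SimConfig(start="2019-01-01 00:00", end="2019-12-31 23:59",
                cadence_switch="2019-07-01 00:00", noise_sd=0.005, seed=42)
sim = simulate_dataset(cfg)

clean, qc_report = flag_anomalies(sim.observed)
print(qc_report)
# 35,288 of 59,085 cells missing (59.7%)

filled, quality, report = impute_table(clean, sim.meta, ImputeConfig())
print(f"filled {report.n_filled} of {report.n_missing_before} gaps")
# filled 35288 of 35288 gaps

imp = clean.isna() & filled.notna()
print(f"MAE {(filled - sim.truth)[imp].abs().stack().mean():.4f} m3/m3")
# MAE 0.0054 m3/m3

print(report.gap_log.head(3).to_string(index=False))
#           timestamp target_id donor_id      score       r
# 2019-01-01 00:00:00   Stipa_1  Stipa_3 217.310222 0.98192
# 2019-01-01 02:00:00   Stipa_1  Stipa_3 217.310222 0.98192
# 2019-01-01 04:00:00   Stipa_1  Stipa_3 217.310222 0.98192

res = paired_regression(make_validation_pairs(sim.truth, cfg, 169))
print(f"slope={res.slope:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}], "
      f"adj R2={res.adj_r_squared:.3f}, n={res.n}")
# slope=0.918 [0.882, 0.953], adj R2=0.939, n=169
```

Reading: after QC, 59.7% of the year's cells were missing; every gap had at
least one eligible donor, and the filled values land within 0.0054 m³/m³ of
the simulated truth on average. Each filled cell is logged with its donor,
the donor's selection score and the model correlation (here *Stipa_3*
serving *Stipa_1*, same-microsite bonus included in the score). The paired
regression recovers a slope near 1 against the reference instrument, as it
should when both only differ by instrument noise.

The same stages are available from the shell:

```bash
soilgaps simulate --seed 42 --start "2019-01-01 00:00" --end "2019-12-31 23:59" --out sim/
soilgaps qc sim/observed.csv --out clean.csv --report qc.json
soilgaps impute clean.csv --out filled.csv --report impute.json
soilgaps validate pairs.csv --out validation.json --plot fit.png
soilgaps run --config pipeline.yaml     # chained stages + per-gap run log
```

A pipeline config lists stages and parameters:

```yaml
seed: 13
out_dir: out/
stages: [simulate, qc, impute, summarize, export]
simulate: {start: "2019-01-01 00:00", end: "2019-06-30 23:59",
           cadence_switch: "2019-04-01 00:00"}
impute: {min_overlap: 50}
export: {formats: [csv, sqlite]}
```

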