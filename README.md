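# polascore

Quantitative scoring of mirror-symmetric cell polarity from two-cell
fluorescence intensity ratios.

Nuclear reporter intensities measured in the two daughters of a dividing cell
sit at different focal depths, which attenuates signal. `polascore` calibrates
that depth effect with a symmetrically expressed control reporter, builds a
95% confidence band around the calibration line, classifies each
polarity-reporter measurement by its depth-corrected residual (normal /
reversed / symmetric orientation; polarized / unpolarized magnitude), and
provides the genotype-level statistics used downstream: Pearson chi-square
tests on phenotype penetrance tables (with integer counts reconstructed from
printed percent + n pairs) and pooled-variance Student t-tests on residual
distributions. A seeded synthetic-data generator with known ground truth makes
every stage testable without microscopy data.

## Layout

| Module | Responsibility |
| --- | --- |
| `polascore.measurements_io` | Data model + delimited-text I/O for measurement and penetrance tables |
| `polascore.calibration` | Depth-attenuation OLS fit, Student-t band, model (de)serialization |
| `polascore.polarity_classification` | Residuals, signed/absolute calls, group summaries, violin plots |
| `polascore.penetrance_stats` | Count reconstruction, chi-square and t tests |
| `polascore.synthetic_data` | Seeded generators for controls, reporters, phenotype tables |

## CLI

```sh
# generate a synthetic dataset (control.csv, reporter.csv, truth.csv, phenotype.csv)
polascore simulate --config sim.yaml --out-dir sim1/ --seed 42

# fit the depth calibration on the symmetric control reporter
polascore calibrate --control sim1/control.csv --out model.txt

# score polarity-reporter measurements against the stored calibration
polascore classify --model model.txt --measurements sim1/reporter.csv \
    --out calls.csv --summary summary.csv --violin signed.png --mode signed

# chi-square enhancement test between two genotypes of a penetrance table
polascore penetrance --table sim1/phenotype.csv \
    --compare "baseline:enhanced" --region anterior --out result.json
```

Measurement CSV schema:
`animal_id,genotype,temperature_c,cell,reporter,intensity_proximal,intensity_distal,z_distance_um`
(`cell` in {Z1, Z4}; `reporter` in {control_nls, pop1, sys1}; `#` lines are
comments; comma or tab delimited). Penetrance CSV schema:
`genotype,region,pct_missing,n[,count_missing]` with `region` in
{anterior, posterior}.

A reference penetrance table ships with the package
(`polascore.load_example_penetrance()`).

## Conventions

- Log ratios are base 10 by default (`polascore.measurements_io.LOG_BASE`);
  classification is invariant to the base as long as it is used consistently.
- The ratio is proximal over distal for both Z1 and Z4, so a positive residual
  means normal orientation for both cells.
- The confidence band has constant half-width `t_crit(df=n-2) * residual_se`
  for all depths — deliberately not a leverage-adjusted prediction interval.
- Residuals exactly on a band boundary classify as symmetric/unpolarized
  (strict inequalities).
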