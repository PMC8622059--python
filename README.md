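# landsec

Composite land ecological security evaluation for multi-year indicator
panels. The package combines:

- **Ratio normalization** of raw years × indicators panels into the
  dimensionless (0, 1] scale, with per-indicator polarity (large-value /
  small-value orientation) taken from an indicator registry;
- **Hierarchical pairwise-comparison weighting**: positive reciprocal
  judgment matrices on the 1–9 scale, principal-eigenvector extraction by
  power iteration (geometric-mean variant available), CI/CR consistency
  control against the standard random-index table, and aggregation of
  local group weights into 17 global weights;
- **Fuzzy comprehensive evaluation**: triangular membership of each
  normalized value against a four-level assessment set (S / RS / RU / U),
  row-stochastic single-factor matrices, and weighted-average synthesis;
- **Pipeline orchestration**: per-year group and comprehensive security
  values (scalar and fuzzy scoring modes, both additive across the three
  groups), level classification, land-use change percentages, and trend
  summaries;
- **Synthetic data generation** with known ground truth (compound growth
  plus multiplicative log-normal noise; consistent judgment matrices from
  target weights) so every stage is testable without external data.

The default registry covers 17 indicators in three groups (resource &
environment S1, economic S2, social S3). Published reference tables (the
normalized 2004–2017 panel, the weight table, and the per-year results)
ship as in-package fixtures at their printed 4-decimal precision.

## CLI

```bash
# generate a synthetic 14-year study-like bundle
landsec simulate --seed 1 --out scratch/bundle

# normalize a raw panel
landsec normalize --panel scratch/bundle/panel.csv --out scratch/normalized.csv

# derive global weights from judgment matrices (top.csv + S1/S2/S3.csv)
landsec weights --matrices scratch/bundle --out scratch/weights.csv

# evaluate a raw panel end to end (default weights: published table)
landsec evaluate --panel scratch/bundle/panel.csv --out scratch/results.csv

# land-use change percentages between two years
landsec landuse-change --panel scratch/bundle/panel.csv \
    --categories S21,S22,S12,S15,S16 --from 2004 --to 2017

# trend summary of a results CSV
landsec report --results scratch/results.csv --out scratch/trend.json
```

All subcommands accept `--config <yaml>` (normalization modes, assessment
levels/anchors, score mode, scalar thresholds) and `-v` for audit logging
of every configuration decision. Exit codes: 0 ok, 1 validation error,
2 numeric error.

## Notes on scoring

The printed per-year component magnitudes in the reference results table
cannot be rederived from the printed normalized panel and weight table —
the membership anchors and level scores behind them were never published.
The pipeline therefore treats the *additivity* of the three group values
to the comprehensive value as the verifiable contract (enforced to 1e-9
in both scoring modes), and exposes anchors, level scores, and scalar
thresholds as explicit configuration rather than constants.
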