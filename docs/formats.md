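# File formats

All tables are tab-separated with a header row; `#`-prefixed lines are
comments. P-values must lie in (0, 1]; standard errors must be positive.
Rows violating these invariants are rejected (with line-numbered log
messages); missing required columns are a hard error.

## GWAS variant / hit tables (`kind="gwas"` / `"hits"`)

| column | type | notes |
| --- | --- | --- |
| `variant` | str | unique id |
| `chrom` | str | chromosome label |
| `pos` | int | 1-based position |
| `pval` | float | association p-value |
| `maf` | float | optional, minor allele frequency |
| `beta`, `se` | float | optional, effect estimate and standard error |

Hit tables are assumed LD-clumped upstream (approximately independent).

## Burden tables (`kind="burden"`)

| column | type | notes |
| --- | --- | --- |
| `gene` | str | gene id |
| `beta` | float | LoF burden effect estimate |
| `se` | float | standard error (> 0) |
| `pval` | float | two-sided p-value |
| `trait` | int | optional trait index (long format) |
| `p_lof` | float | optional aggregate LoF frequency |

## Gene annotation tables (`kind="genes"`)

| column | type | notes |
| --- | --- | --- |
| `gene` | str | gene id |
| `chrom` | str | chromosome |
| `start`, `end` | int | 1-based inclusive span |
| `midpoint` | int | optional; computed as `(start + end) // 2` when absent |
| `mu_l` | float | optional mutational target size (mu x L) |
| `s_het` | float | optional selection coefficient |

## LD blocks (BED)

Standard 3-column BED, 0-based half-open, no header. Converted on read to
the internal 1-based inclusive convention (`start+1`, `end`). Blocks must
not overlap within a chromosome.

## Frequency-distribution tables

Written by `FrequencyDistribution.to_tsv()` / the `sim-freqs` subcommand:
a `#` header line recording `n_diploids`, `mut_rate`, `s_het` and the
conditioning flag, then columns `count`, `frequency`, `mass`.

## Configuration files

Plain `key: value` text (a YAML mapping). Keys are the dataclass field
names of the relevant configuration (for example `n_shet_values`,
`sample_haploids` for `sim-realized`) plus the shared grid keys
`n_diploids`, `mut_rate`, `grid_points`, `grid_lo`, `grid_hi`.
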