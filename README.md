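# pvcomp

Compare p-value tables produced by multiple omics analysis methods.

Many statistical methods applied to the same omics dataset (differential
expression, association tests, rare-variant tests, …) produce different
marker rankings. `pvcomp` takes a single tab-separated table — one row
per marker, one column of p-values per method — and produces three
comparison views:

* **pairwise** — all-pairs scatter matrix of the methods' p-values
  (−log10 scale by default) with Pearson/Spearman correlation
  coefficients;
* **detail** — a two-method comparison: Venn partition of markers into
  both / A-only / B-only / neither at chosen thresholds, a
  significance-threshold sweep table, a class-colored scatter, and the
  four marker lists;
* **multi** — a color-coded HTML significance table for any subset of
  methods (red = significant at that method's own threshold, deeper
  color = smaller p), extraction of commonly-significant markers, and
  optional Fisher's combined p-values per marker (with a standing
  caution: combining p-values from one dataset analyzed by several
  methods violates the independence assumption).

It also detects marker types (dbSNP rsIDs, gene symbols, Ensembl IDs)
and constructs NCBI / DAVID annotation URLs without any network access,
and ships two fully deterministic simulators so everything is testable
offline.

## Input format

UTF-8 TSV with a mandatory header row. The first column holds marker
identifiers (its header label is arbitrary); the remaining columns hold
decimal p-values (scientific notation accepted), one column per method.
`NA`, `.` or an empty cell mark a missing value. At least two method
columns are required; `pvcomp merge` aligns one-method-per-file inputs
into this format.

```text
gene	t_test	wilcoxon	permutation
Cyyr1	1.2e-06	4.1e-05	9.99e-04
Il9	0.0031	0.0018	0.0049
```

## CLI

```sh
# make a synthetic table to play with
pvcomp simulate --out demo.tsv --markers 2000 --methods 4 --rho 0.6 \
    --pi1 0.1 --mu 2.5 --seed 1

# all-pairs correlation view (top 1500 markers by average p-value)
pvcomp pairwise demo.tsv --out out/pairwise --top-n 1500

# two-method detail view with a threshold sweep from 5% to 0.1%
pvcomp detail demo.tsv --out out/detail \
    --method-a method_1 --method-b method_2 \
    --alpha-a 0.01 --sweep 0.05,0.01,0.005,0.001

# multi-method table with per-method thresholds and combined p-values
pvcomp multi demo.tsv --out out/multi --alpha 0.001 \
    --alpha-per-method method_3=0.01 --combine

# annotation links (no network access; URLs only)
pvcomp annotate demo.tsv --out annotations.tsv

# align one-method-per-file tables
pvcomp merge a.tsv b.tsv --out combined.tsv
```

Every subcommand writes a `run_config.json` run-log next to its outputs;
repeated runs on the same inputs produce byte-identical TSV/HTML.

## Library

```python
import pvcomp

m = pvcomp.read_result_table("demo.tsv")
m = pvcomp.filter_missing(m, pvcomp.MissingPolicy.DROP_ANY_MISSING)
top = pvcomp.select_top(m, pvcomp.SelectionSpec("count", 1500))

corr = pvcomp.correlation_matrix(top, transform="neglog10")
part = pvcomp.classify_pair(top, "method_1", "method_2", 0.01)
sweep = pvcomp.threshold_sweep(top, "method_1", "method_2")

table = pvcomp.build_multi_table(top, alpha=0.001, with_combined=True)
hits = pvcomp.common_significant(top, alpha=0.001)
res = pvcomp.fisher_combine([1e-4, 3e-3, 0.02])
```

## Tests and acceptance checks

```sh
python -m pytest tests/                      # full suite (~20 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance suite: brute-force
oracles for the Venn partition and the threshold sweep, closed-form
checks of Fisher's method, null calibration and parameter recovery of
the simulators, and byte-level CLI determinism. `scripts/acceptance.py`
re-runs a condensed version of those checks from scratch and writes an
empty JSON object (this build defines no numeric acceptance targets;
acceptance is property-based), exiting non-zero if any check fails.
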