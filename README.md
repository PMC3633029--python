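# gcdiv

Estimating the clonal diversity of germinal centers (GCs) from
immunohistological section data of two-phenotype chimeric animals, and from
clone-abundance samples of single GC sections.

The package implements:

* **`gcdiv.chimera_model`** — analytic section-classification probabilities.
  The *basic* model treats a whole GC founded by `n` cells from a pool with
  phenotype-B fraction `p` (pure-A/pure-B/mixed fractions
  `q**n, p**n, 1 - q**n - p**n`). The *extended* model adds hypergeometric
  sampling of an `m`-cell section from an `M`-cell GC, scoring-error
  thresholds `l_TA`/`l_TB` (minority cells that can be overlooked when a
  section is scored pure), and Poisson-distributed founder numbers with mean
  `λ = ⟨n⟩` (the n = 0 term omitted, not renormalized).
* **`gcdiv.fitting`** — χ² consistency statistics on the percent scale,
  the internal-consistency report for a chimera dataset, and an exhaustive
  χ² grid search over `(⟨n⟩, l_TB%, l_TA%)` returning the global and all
  local minima.
* **`gcdiv.diversity`** — clone-richness estimation from abundance samples:
  a two-stage Yule–Simon / mixed-Poisson maximum-likelihood estimator with a
  self-consistent unseen-clone correction, the nonparametric ACE estimator
  (with Chao1 fallback at zero coverage), and a per-GC report table.
* **`gcdiv.simulate`** — a Monte-Carlo forward simulator of GC seeding,
  expansion, sectioning and scoring (the brute-force cross-check of the
  analytic model), and a synthetic stained-section renderer on a hexagonal
  lattice.
* **`gcdiv.interface`** — TSV/JSON readers and writers plus the `gcdiv` CLI.

## CLI

```bash
# internal-consistency analysis of the classic p = 0.21 chimera dataset
gcdiv consistency --p 0.21 --pct-a 14 --pct-b 6 --pct-mix 80

# expected section fractions, fixed n or Poisson lambda (or a lambda sweep TSV)
gcdiv expected --n 2 --gc-size 10 --section-size 4 --l-ta 1 --l-tb 1
gcdiv expected --gc-size 5000 --section-size 100 --l-tb 10 \
      --lam-min 1 --lam-max 40 --out sweep.tsv

# chi-square grid search (defaults: lambda 1..40, l_TB 10..15%, l_TA 50..65%)
gcdiv fit --p 0.21 --pct-a 14 --pct-b 6 --pct-mix 80 \
      --out minima.json --surface-out surface.tsv

# richness estimates from a clone-abundance table
# (TSV columns: clone_id, count[, sample_id]; or a bare counts vector)
gcdiv diversity clones.tsv --out report.tsv --json-out report.json

# Monte-Carlo simulation and stained-section rendering
gcdiv simulate --lam 19 --l-tb 20 --l-ta 124 --n-gcs 100000 --seed 1
gcdiv render --type-a-fraction 0.4 --seed 0 --out panel.tsv --png panel.png
```

Observed classification values are accepted as percentages (summing to ~100)
or fractions (summing to ~1); ambiguous inputs are rejected. Subcommand
options can also come from a YAML/JSON file via `--config`; explicit flags
win over file values. Every stochastic run echoes its seed in its output.

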