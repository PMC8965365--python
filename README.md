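# offsetlab

**Truth-known evaluation of genomic-offset prediction.**

"Genomic offset" methods promise to predict, from present-day genomes and
environments, how maladapted a population will be after environmental change.
The most popular flavour builds gradient-forest *turnover functions* — curves
describing how allele frequencies turn over along each environmental gradient
— and reads the offset between two environments as a distance in
cumulative-importance space. These predictions are widely used, and almost
never validated against realized fitness, because in nature the truth is
unknowable on management timescales.

`offsetlab` makes the truth knowable. It simulates spatial metapopulations
forward in time with explicit genotype → phenotype → fitness maps, computes
the gradient-forest-style **GF Offset** alongside competing metrics
(Weir–Cockerham F_ST, Euclidean and Mahalanobis environmental distances, each
over all or causal-only inputs), and then scores every metric against the one
thing simulations provide for free: the true common-garden fitness of every
population in every environment.

Three headline findings the pipeline reproduces:

1. **Drift masquerades as offset.** With purely neutral loci, GF Offset is
   systematically larger for small demes — predicted "maladaptation" that is
   nothing but genetic drift (negative correlation between deme size and
   offset, regardless of whether sizes increase or decrease along the
   landscape).
2. **Turnover curves are shape, not causation.** Constructed allele-frequency
   clines show that a nonmonotonic cline accrues importance only at the
   gradient edges, and a deme can receive a strictly positive predicted
   offset between two environments where its allele frequencies are
   *identical*.
3. **Knowing the causal environments beats knowing the genome.** At
   range-edge gardens, the plain Euclidean distance over the causal
   environmental variables ranks populations' realized fitness at least as
   well as GF Offset, and both beat F_ST and all-variable environmental
   distance.

## Worked example

One desk-scale replicate of Case 1 (two orthogonal linear gradients, polygenic
two-trait architecture), end to end:

```python
import numpy as np
from offsetlab.pipeline import analyze_replicate, transplant_run_config
from offsetlab.transplant import core_edge_summary

cfg = transplant_run_config("case1", master_seed=101)
res = analyze_replicate(cfg, replicate=0)

print(f"local adaptation    {res['local_adaptation']:.3f}")
print(f"sympatric advantage {res['sympatric_advantage']:.3f}")

ev = res["evaluation"].copy()
ev["rho"] = ev["rho"].abs()
print(core_edge_summary(ev).round(3).to_string(index=False))
```

Output (about half a minute on one CPU):

```
local adaptation    0.282
sympatric advantage 0.464
       metric  core  edge
       ed_all 0.202 0.220
    ed_causal 0.893 0.941
   fst_causal 0.783 0.835
   fst_genome 0.799 0.835
gf_genome_all 0.888 0.931
       md_all 0.211 0.385
    md_causal 0.894 0.941
```

Reading the table: each row is one offset metric; `edge`/`core` are the mean
|Spearman ρ| between that metric and true common-garden fitness across
range-edge and range-core gardens. `ed_causal` (Euclidean distance over the
two causal environments) and `gf_genome_all` (GF Offset from all SNPs and all
fourteen environmental variables) track fitness almost perfectly at the edge;
`ed_all`/`md_all` (distances over all fourteen variables, twelve of which are
decoys) collapse.

The same machinery is scriptable from the shell:

```bash
offsetlab run-all --scenario case1 --preset desk --seed 101 --out results/demo
offsetlab thought --experiment 4 --seed 0 --out results/thought
```

## Repository layout

- `src/offsetlab/` — the library:
  - `landscape.py` grid, deme sizes, causal/decoy environmental gradients
  - `simulate.py` forward Wright–Fisher simulator (neutral, single-locus,
    polygenic architectures), sampling, VCF export
  - `gf.py` turnover-function engine and GF Offset
  - `metrics.py` Weir–Cockerham F_ST, environmental distances
  - `transplant.py` common-garden fitness, local adaptation, per-garden metric
    evaluation, deme-size confounding analysis
  - `clines.py` constructed-cline thought experiments
  - `pipeline.py`, `cli.py`, `io.py` orchestration, CLI, text formats
- `analysis/` — numbered narrative drivers writing `results/`:
  `01_thought_experiments.py`, `02_drift_confounding.py`,
  `03_single_locus.py`, `04_multilocus_cases.py`, `05_offset_evaluation.py`
- `tests/` — unit, property and acceptance suites
- `scripts/acceptance.py` — recomputes the quantitative acceptance targets
- `docs/methods.md` — full model description, design decisions, scaling

## Reproduction

Every stage is seeded: one master seed per run, with deterministic per-stage,
per-replicate substreams (`pipeline.stage_seed`), and per-SNP substreams keyed
on SNP identity inside the turnover engine. Re-running any configuration with
the same seed reproduces every artifact byte-for-byte (checksums in each run's
`manifest.json`).

```bash
# the full desk-scale analysis sequence (minutes each on one CPU)
python analysis/01_thought_experiments.py
python analysis/02_drift_confounding.py --replicates 10
python analysis/03_single_locus.py
python analysis/04_multilocus_cases.py --replicates 3
python analysis/05_offset_evaluation.py

# test suite (the acceptance tests simulate ~33 replicates; ~15 min on 1 CPU)
python -m pytest -q

# quantitative acceptance targets
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The `full` preset (`--preset full`) holds the full-scale parameters
(N = 10,000; 10 linkage groups × 50,000 sites; 3,000 multilocus generations);
it is provided for fidelity but takes hours to days per replicate on one CPU.
Scaled-down parameter choices and their calibration are documented in
`docs/methods.md`.
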