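# mrsub

Per-site estimation of the **time to the most recent substitution** on a
target species' lineage from multiple genome alignment columns.

Given a rooted binary phylogenetic tree with branch lengths, a nucleotide
substitution model and one alignment column, `mrsub` computes exactly, by
dynamic programming over the tree:

- `t_mrs` — the posterior expected time (substitutions/site) from the
  present back to the most recent substitution on the target leaf-to-root
  path,
- `sigma` — its posterior standard deviation,
- `q` — the posterior probability that no substitution occurred anywhere on
  that path,
- `Z` — the column likelihood.

Around that core the package provides: maximum-likelihood training of a
six-parameter strand-symmetric rate matrix plus all branch lengths (exact
inside–outside gradients, L-BFGS-B); forward simulation with true-history
annotation and gap masking; posterior sampling of substitution histories
(the correctness oracle for the exact algorithm); 'reconstruction' and
'alignment' baseline estimators and an evaluation harness; assignment of
confident sites to concestor intervals; and hypergeometric tissue-by-interval
enrichment ranked by Z-score.

## Library quick start

```python
from mrsub import TreeEngine, default_model, read_newick

tree = read_newick("tree.nwk")                  # rooted, binary, branch lengths
model = default_model().normalized()            # packaged strand-symmetric rates
engine = TreeEngine(tree, model, target="hg38")

est = engine.estimate({"hg38": "A", "panTro4": "G", "mm10": "A"})
print(est.t_mrs, est.sigma, est.q)
```

Species absent from a column, gaps and IUPAC ambiguity codes are treated as
missing data (their subtrees marginalise away — estimates equal those on the
pruned tree). Columns whose *target* symbol is a gap or ambiguous are
flagged `skipped`.

## Command line

All subcommands run offline; `make-fixtures` generates a complete synthetic
bundle (tree, model, MAF, truth table, BED, tissue labels) to try them:

```sh
mrsub make-fixtures --outdir fx --n-taxa 10 --n-sites 500 --seed 1
mrsub train  --maf fx/alignment.maf --tree fx/tree.nwk --target sp1 \
             --out-model fitted.txt --out-tree fitted.nwk
mrsub score  --maf fx/alignment.maf --tree fx/tree.nwk --target sp1 \
             --model fitted.txt --out sites.tsv
mrsub assign-intervals --sites sites.tsv --out assigned.tsv
mrsub enrich --sites assigned.tsv --bed fx/regions.bed \
             --tissues fx/tissues.tsv --out enrichment.tsv
mrsub simulate --tree fx/tree.nwk --target sp1 -n 1000 --seed 2 \
             --gap-probability 0.6 --out-maf sim.maf --out-truth truth.tsv
mrsub sample-posterior --maf sim.maf --tree fx/tree.nwk --target sp1 \
             --n-samples 10000 --n-points 200 --seed 3 --out posterior.tsv
```

Exit codes: 0 ok, 2 input error, 3 numerical failure.

## Module map

| module | contents |
| --- | --- |
| `mrsub.rates` | strand-symmetric/GTR generators, eigensystem, equilibrium, `K`/`K'` kernels, (de)serialisation |
| `mrsub.edge` | closed-form single-branch estimators + discrete-chain oracle |
| `mrsub.tree` | flat-array rooted binary trees, Newick I/O, lineages, pruning |
| `mrsub.engine` | inside/outside tables, per-column `(t_mrs, sigma, q, Z)`, ancestral reconstruction |
| `mrsub.train` | ML fitting of rates + branch lengths with exact gradients |
| `mrsub.simulate` | forward simulation, gap masks, posterior history sampling, baselines, evaluation |
| `mrsub.intervals` | concestor tables, interval assignment, region mapping, enrichment |
| `mrsub.maf` | MAF/BED/site-table I/O, reservoir column sampling |
| `mrsub.fixtures` | synthetic trees and complete offline fixture bundles |
| `mrsub.cli` | the `mrsub` command |
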