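# refstab

Reference-gene stability evaluation for RT-qPCR.

Relative quantification by RT-qPCR stands or falls with its reference genes
(RGs): a "housekeeping" gene whose expression drifts across tissues or
developmental stages distorts every profile normalized to it. `refstab` is
for researchers screening a candidate RG panel across a sample series — for
example fruit, floral, seed and vegetative tissues of a crop plant — who
need a defensible, reproducible ranking of candidates and a multi-gene
normalization factor for their target genes.

Given a gene x sample x replicate table of quantification cycles (Ct), the
package computes four established stability statistics:

- **comparative ΔCt** — mean over partner genes of SD_s(Ct_j − Ct_k);
- **geNorm** — M_j = mean_k SD_s(log2 q_j/q_k), with iterative exclusion of
  the least stable gene and the pairwise variation V(n/n+1);
- **NormFinder** — model-based stability values from an intra-/intergroup
  variance decomposition of log2 quantities;
- **BestKeeper** — SD, CV% and geometric mean of raw Ct plus correlation
  with the per-sample geometric-mean index;

and aggregates the four rankings into a consensus score per gene, the
geometric mean of its competition ranks (lower = more stable). It also fits
dilution-series standard curves, `E(%) = (10^(−1/slope) − 1) × 100`, and
normalizes target-gene expression to the geometric mean of a chosen RG set.
A seeded synthetic-Ct generator with known ground truth backs the test
suite. See `docs/methods.md` for the full statistical account.

## Worked example

```python
from refstab import default_config, generate_ct_dataset
from refstab.pipeline import PipelineConfig, run_pipeline

m, truth = generate_ct_dataset(default_config(seed=1))   # 11 genes x 23 samples x 4 reps
results = run_pipeline(PipelineConfig(matrix=m, outdir="out"))

comp = results["All samples"].comprehensive
for g in comp.order():
    print(f"{g:7s} geomean={comp.display[g]:5.2f} rank={comp.final_rank[g]}")
```

prints

```
HIS3    geomean= 1.73 rank=1
ACT     geomean= 2.51 rank=2
TIP41   geomean= 2.78 rank=3
TUA3    geomean= 3.08 rank=4
RPL18   geomean= 3.31 rank=5
RPL4    geomean= 4.90 rank=6
UGPase  geomean= 7.45 rank=7
SAMDC   geomean= 8.21 rank=8
GAPDH   geomean= 8.24 rank=9
PIP2    geomean=10.00 rank=10
18S     geomean=11.00 rank=11
```

Each line is one candidate gene: `geomean` is the geometric mean of its four
per-method ranks over all 23 samples of this simulated dataset (HIS3's 1.73
comes from ranks 1, 3, 3, 1), and `rank` is the final consensus position.
The genes simulated with low instability (here the ribosomal-protein,
histone, tubulin candidates) land at the top; those simulated with strong
tissue dependence (PIP2, 18S, SAMDC) land at the bottom. `out/` then
contains, per subset, the per-method tables (`stability_long.csv`), the
consensus (`comprehensive.csv`) and a "value (rank)" grid (`report.txt`),
plus a run log of every analysis switch in effect.

The same pipeline runs from the shell:

```
refstab simulate --seed 1 --out ct.csv
refstab evaluate --input ct.csv --outdir out
refstab efficiency --input curves.csv
refstab normalize --input ct.csv --target EjCDKB1 --rg RPL4,RPL18,HIS3 --out expr.csv
```

Real data drop in the same way: `--input` accepts long
(`gene,sample,replicate,ct`) or wide (`sample_rep` columns) delimited text,
with sample subsets and group labels as small YAML files.

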