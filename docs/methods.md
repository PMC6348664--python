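# Methods

`refstab` evaluates candidate reference genes (RGs) for RT-qPCR
normalization from a table of quantification-cycle (Ct) values, ranks them
with four established stability statistics, aggregates the rankings into a
consensus, and uses the selected RG set to normalize target-gene expression.
This note records the statistical definitions, the defaults and why they were
chosen, the synthetic data model behind the test suite, and known
limitations.

## Data model

The universal container is a gene x sample x technical-replicate Ct array
(`CtMatrix`). Ct is kept on the raw cycle scale; every transform (replicate
collapse, subsetting, quantity conversion) is an explicit operation, never
hidden in I/O. Missing wells are carried as NaN and never silently dropped:
replicate collapse summarises the present wells (and warns when a cell is
entirely empty), while the stability statistics reject missing cells
outright. Imputation would change the standard deviations the methods are
built on, so it is deliberately not offered.

Replicate collapse defaults to the arithmetic mean of Ct (a median option
exists for outlier-heavy plates). Averaging on the cycle scale corresponds
to a geometric mean of quantities, the conventional choice for technical
replicates of the same reaction.

Relative quantities are `q[g,s] = E_g ** (minCt_g - Ct[g,s])` with per-gene
amplification factor `E_g` (2.0 = 100% efficiency), so each gene's most
abundant sample scores exactly 1. Efficiency defaults to 2.0 for every gene;
measured standard-curve factors (e.g. the bundled panel values) can be
supplied instead. Efficiencies enter only through this transform.

## The four stability statistics

All standard deviations are sample SDs (ddof = 1). Logarithms are base 2
throughout; any fixed base rescales the geNorm/NormFinder values by a
constant and leaves every ranking unchanged (tested).

**Comparative delta-Ct.** For genes *j*, *k* the pair dispersion is the SD
over samples of `Ct_j - Ct_k`; the stability of *j* is the mean pair
dispersion over all partners *k*. A per-sample loading shift (template
input, RT yield) is common to both genes in every pair and cancels exactly.

**geNorm.** On log2 quantities, `V[j,k] = SD_s(log2 q_j/q_k)` and
`M_j = mean_k V[j,k]`. The ranking removes the gene with the largest M,
recomputes M on the survivors, and repeats until two genes remain. Each
gene's reported value is its M at the step of its elimination; the final
pair are mutually indistinguishable by the statistic, so both receive rank 1
(and the next-best gene rank 3, competition style). Ties in the elimination
step remove the later gene in input order, deterministically. The
pairwise-variation series `V(n/n+1)` — the SD over samples of
`log2(NF_n/NF_{n+1})`, where `NF_n` is the geometric mean of the *n* best
genes' quantities — is reported for choosing how many RGs to carry; the
package deliberately applies no hard cutoff (the conventional 0.15 guideline
is the user's call).

**NormFinder.** The model on `y = log2 q` is additive: gene effect + sample
effect + noise with gene-specific variance. Ungrouped, residuals after
double centering estimate each gene's variance, but centering over G genes
leaks a fraction of every gene's noise into every row; the estimates

    MS_g = sum_s r[g,s]^2 / (n-1)
    var_g = G/(G-2) * ( MS_g - sum(MS)/(G(G-1)) )

are unbiased under the model (derived from the centering algebra), floored
at 0, and the stability value is `SV_g = sqrt(var_g)`. With sample groups,
per-group variances are estimated the same way, group means are
double-centered over genes x groups to give the intergroup bias `d[g,j]`,
and an empirical-Bayes step shrinks each bias by
`gamma^2 / (gamma^2 + var[g,j]/n_j)`, where `gamma^2` is the
method-of-moments estimate of the bias variance. The stability value
averages `|shrunk bias| + posterior SD` over groups, so it combines
systematic between-group differences with within-group noise. A grouped call
on a subset with a single group label has no intergroup component and
reduces to the ungrouped analysis. Groups of size 1 are rejected (their
within-group variance is inestimable). At least 3 genes are required (the
G-2 factor).

**BestKeeper.** Descriptive statistics on raw Ct: per-gene SD about the
arithmetic mean, CV% = 100*SD/mean, geometric mean Ct, and the Pearson
correlation of each gene's Ct with the BestKeeper index (the per-sample
geometric mean of all genes' Ct). Ranking uses SD by default; CV is a switch
because the two disagree when baseline levels differ (a +5-cycle shift
leaves SD unchanged but lowers CV). A constant gene's correlation is
undefined and reported as missing with a warning. Unlike the three relative
methods, BestKeeper works on raw Ct, so shared per-sample loading inflates
every gene's SD — worth remembering when loading variation is large.

## Consensus ranking

Per method, genes receive competition ("1224") ranks: ties share the
minimum rank and the next distinct value skips by the tie count. The
consensus value of a gene is the unweighted geometric mean of its per-method
ranks, in the fixed order delta-Ct, BestKeeper, NormFinder, geNorm; lower is
more stable. Display values are rounded half-up to two decimals, matching
how published consensus tables print them, but ordering always uses the
unrounded values (final-rank ties again use the competition rule). The
bundled loquat survey table reproduces this arithmetic cell-for-cell on all
internally consistent entries (54 of 55; one floral-subset cell carries a
typographical rank inconsistency in its source and is flagged in the CSV).

## Standard curves and target normalization

A dilution series is fit by ordinary least squares of Ct on log10 template
amount; efficiency is `E(%) = (10**(-1/slope) - 1) * 100`, so the perfect
doubling slope `-1/log10(2) ~ -3.3219` gives exactly 100%. A non-negative
slope marks the curve invalid rather than raising, so batch fits can flag
failures. At least three distinct dilution levels are required.

Target expression uses the efficiency-corrected ratio with multi-RG
normalization: per sample, the normalization factor NF is the geometric mean
of the RG set's relative quantities, and each biological replicate's
expression is `E_target ** (minCt - Ct) / NF`, reported as mean ± SD over
biological replicates, optionally rescaled so a named calibrator sample
equals 1. With all efficiencies fixed at 2 and a calibrator this reduces to
the classic 2^(-ddCt). A per-sample Ct shift applied to target and all RGs
cancels exactly at efficiency 2 (tested). Error propagation from technical
replicates into the biological-replicate SD is out of scope.

## Synthetic data generator

The generator draws, on the cycle scale,

    Ct[g,s,r] = baseline_g + shift_{g,s} + load_s + noise_{g,s,r}

with `shift ~ N(0, instability_sd_g)` per gene x sample — or per gene x
group when groups are declared, so "unstable" means tissue-dependent —
`load ~ N(0, loading_sd)` shared by all genes of a sample, and
`noise ~ N(0, tech_sd)` per well. Everything is reproducible from one seed.
A target gene can be spiked in with a programmed log2 expression profile
(one extra log2 unit = one cycle earlier), sharing the dataset's realized
loading effects and noise level.

Defaults emulate a realistic multi-tissue RG screen: 11 candidate genes x
23 samples x 4 technical replicates, baselines spread over 17–25 cycles
(rRNA most abundant, tubulin least), per-gene instability SDs from 0.15
(stable ribosomal-protein genes) to 1.2 cycles (clearly tissue-dependent
candidates), loading SD 1.0, technical SD 0.15. The 23 samples carry four
tissue-group labels (fruits, floral tissues, ovules and seeds, vegetative
tissues); the bundled subset config adds the all-samples union. The sample
ids are this package's own naming of a 5+7+3+3+5 tissue design.

What the generator does *not* emulate: amplification-efficiency drift,
PCR inhibition, fluorescence-curve artefacts and Cq-calling, non-normal
outliers, and correlated co-regulation between candidate genes. Passing
parameter-recovery tests therefore show that the statistics recover the
generative model they assume — not that any real panel satisfies that
model.

### What the recovery experiments show

With 5 genes of instability SDs (0.05, 0.1, 0.2, 0.4, 0.8), 30 samples,
loading SD 1.0 and technical SD 0.1 over 20 seeded runs, the mean Spearman
correlation between the programmed instability order and each method's
ranking is ~0.97 for delta-Ct, geNorm and NormFinder. Identifying the single
most stable gene is harder: SDs of 0.05 vs 0.1 cycles differ by far less
than the methods' own estimation noise at 5 genes and 30 samples (pairwise
statistics dilute the contrast through the unstable partners; sample
centering leaks the 0.8-SD gene into every residual; geNorm cannot separate
its final pair at all; BestKeeper mostly sees the loading), so the
four-method consensus crowns the true best gene in roughly three quarters of
runs rather than nearly always. The spiked-target experiment shows the
practical consequence of RG choice: a single-peak profile normalized to a
zero-instability RG set recovers its peak position in every seeded run,
while a high-instability RG set yields a clearly larger mean absolute log2
profile error.

## Numerical choices and degenerate inputs

- Sample SD (ddof = 1) everywhere a dispersion is reported.
- Zero-variance inputs are legal where they are meaningful (a constant gene
  has delta-Ct stability 0) and flagged where they are not (undefined
  BestKeeper correlation -> NaN + warning).
- NormFinder variance estimates are floored at 0 before the square root.
- geNorm elimination ties break deterministically toward the later gene in
  input order.
- Competition ranks are used for every ranking, including final consensus
  ties.
- Display rounding is decimal half-up (1.005 -> 1.01), two decimals.

## Problem sizes in the test suite

Oracle-equivalence checks run 200 random instances up to 6 genes x 10
samples against loop-level brute-force reimplementations (tolerance 1e-10
relative). Recovery experiments use 20 seeded datasets of 5 x 30 x 4 (and
6 x 21 x 3 for the spiked-target contrast); the noise-calibration check uses
10^4 replicate draws. These sizes give stable statistics while keeping the
whole suite fast.

## Known limitations

- Stability methods require complete (no-missing) subsets; users must
  collapse or drop before analysis.
- The grouped NormFinder variant follows the empirical-Bayes decomposition
  described above; other implementations of the grouped method differ in the
  exact combination rule, so grouped SVs should be compared across tools
  with care.
- BestKeeper's published tool also reports medians/MADs and uses pairwise
  correlations among genes; this implementation reports the SD/CV/geomean/
  index-correlation core that stability ranking needs.
- V(n/n+1) is reported without a recommendation threshold.
- Instrument-native exports (e.g. LightCycler files) are not parsed; inputs
  are plain delimited text.
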