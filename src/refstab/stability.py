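"""The four per-gene expression-stability statistics.

* **comparative delta-Ct** — mean, over all partner genes, of the sample
  standard deviation of pairwise Ct differences;
* **geNorm** — M value (mean pairwise log-ratio SD) with iterative exclusion
  of the least stable gene, plus the V(n/n+1) pairwise-variation series;
* **NormFinder** — model-based variance decomposition on log quantities,
  ungrouped or with sample groups (intra-/intergroup variation);
* **BestKeeper** — descriptive Ct statistics (SD, CV%, geometric mean) and
  correlation with the per-sample geometric-mean index.

All statistics use the sample standard deviation (ddof=1). Logarithms are base
2; any fixed base gives identical rankings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aggregate import competition_ranks
from .ct_data import CtMatrix, CtValidationError

__all__ = [
    "QuantityMatrix",
    "StabilityTable",
    "BestKeeperStats",
    "to_relative_quantity",
    "delta_ct_stability",
    "genorm_m_values",
    "genorm_ranking",
    "genorm_pairwise_variation",
    "normfinder_stability",
    "bestkeeper_stats",
    "bestkeeper_ranking",
]


@dataclass
class QuantityMatrix:
    """Relative quantities on a linear scale, one value per gene and sample.

    Built from Ct via ``q = E ** (min_ct - ct)`` with per-gene efficiency
    ``E`` (2.0 = perfect doubling), so each gene's most abundant sample has
    quantity exactly 1.
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray  # (G, S), all > 0
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.genes), len(self.samples)):
            raise CtValidationError(
                f"q shape {self.q.shape} does not match gene/sample counts"
            )
        if not np.all(np.isfinite(self.q)) or np.any(self.q <= 0):
            raise CtValidationError("all relative quantities must be finite and > 0")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.genes, columns=self.samples)


@dataclass
class StabilityTable:
    """Per-gene stability values and competition ranks for one method/subset.

    ``values`` are method-specific (cycles for delta-Ct and BestKeeper SD,
    dimensionless for geNorm M and NormFinder SV); rank 1 is most stable.
    """

    method: str
    subset_name: str
    values: dict[str, float]
    ranks: dict[str, int]

    @classmethod
    def from_values(
        cls, method: str, subset_name: str, values: Mapping[str, float]
    ) -> "StabilityTable":
        vals = dict(values)
        return cls(method, subset_name, vals, competition_ranks(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "subset": self.subset_name,
                "gene": list(self.values),
                "value": list(self.values.values()),
                "rank": [self.ranks[g] for g in self.values],
            }
        )


def _collapsed_complete(m: CtMatrix, op: str) -> np.ndarray:
    x = m.values2d()
    if np.isnan(x).any():
        cells = [
            (m.genes[g], m.samples[s]) for g, s in zip(*np.nonzero(np.isnan(x)))
        ]
        raise CtValidationError(f"{op}: missing Ct cells not allowed: {cells}")
    return x


def to_relative_quantity(
    m: CtMatrix,
    efficiencies: float | Mapping[str, float] | None = None,
) -> QuantityMatrix:
    """Transform collapsed Ct to relative quantities, min-Ct calibrated.

    ``efficiencies`` may be a single amplification factor, a per-gene mapping
    (genes absent from the mapping fall back to 2.0), or None for 2.0
    throughout. Efficiency as a factor must exceed 1 (1.93 = 93%
    efficiency in percent terms).
    """
    x = _collapsed_complete(m, "to_relative_quantity")
    if efficiencies is None:
        eff = {g: 2.0 for g in m.genes}
    elif isinstance(efficiencies, Mapping):
        eff = {g: float(efficiencies.get(g, 2.0)) for g in m.genes}
    else:
        eff = {g: float(efficiencies) for g in m.genes}
    bad = {g: e for g, e in eff.items() if e <= 1.0}
    if bad:
        raise CtValidationError(f"amplification factors must be > 1: {bad}")
    e = np.array([eff[g] for g in m.genes])[:, None]
    q = e ** (x.min(axis=1, keepdims=True) - x)
    return QuantityMatrix(list(m.genes), list(m.samples), q, eff)


# -- comparative delta-Ct ----------------------------------------------


def delta_ct_stability(m: CtMatrix, subset_name: str = "all") -> StabilityTable:
    """Comparative delta-Ct stability: for each gene, the mean over all other
    genes of the sample SD of their per-sample Ct difference.

    A shared per-sample shift (pipetting/loading) cancels in every pairwise
    difference, so the statistic reflects relative instability only.
    """
    x = _collapsed_complete(m, "delta_ct_stability")
    G, S = x.shape
    if G < 2:
        raise CtValidationError("delta-Ct stability needs at least 2 genes")
    if S < 2:
        raise CtValidationError("delta-Ct stability needs at least 2 samples")
    values = {}
    for j, gene in enumerate(m.genes):
        sds = [np.std(x[j] - x[k], ddof=1) for k in range(G) if k != j]
        values[gene] = float(np.mean(sds))
    return StabilityTable.from_values("delta_ct", subset_name, values)


# -- geNorm --------------------------------------------------------------


def genorm_m_values(q: QuantityMatrix) -> dict[str, float]:
    """geNorm M: mean over partner genes of the SD of the pairwise log2 ratio."""
    G, S = q.q.shape
    if G < 2 or S < 2:
        raise CtValidationError("geNorm M needs at least 2 genes and 2 samples")
    a = np.log2(q.q)
    out = {}
    for j, gene in enumerate(q.genes):
        sds = [np.std(a[j] - a[k], ddof=1) for k in range(G) if k != j]
        out[gene] = float(np.mean(sds))
    return out


def genorm_ranking(q: QuantityMatrix, subset_name: str = "all") -> StabilityTable:
    """geNorm iterative-exclusion ranking.

    M values are recomputed on the surviving gene set and the gene with the
    largest M is removed (ties: the later gene in input order) until two
    remain. Each gene's reported value is its M at the step of its
    elimination; the final pair share rank 1 and the last-step M, and the
    next-best gene receives rank 3.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise CtValidationError(
            "geNorm ranking needs >= 3 genes; use genorm_m_values for 2"
        )
    surviving = list(genes)
    values: dict[str, float] = {}
    ranks: dict[str, int] = {}
    frame = q.frame()
    next_rank = len(genes)
    while len(surviving) > 2:
        sub = QuantityMatrix(
            surviving,
            list(q.samples),
            frame.loc[surviving].to_numpy(),
            {g: q.efficiencies[g] for g in surviving},
        )
        m_vals = genorm_m_values(sub)
        worst = max(surviving, key=lambda g: (m_vals[g], surviving.index(g)))
        values[worst] = m_vals[worst]
        ranks[worst] = next_rank
        next_rank -= 1
        surviving.remove(worst)
    pair = QuantityMatrix(
        surviving,
        list(q.samples),
        frame.loc[surviving].to_numpy(),
        {g: q.efficiencies[g] for g in surviving},
    )
    final_m = genorm_m_values(pair)
    for g in surviving:
        values[g] = final_m[g]
        ranks[g] = 1
    values = {g: values[g] for g in genes}
    ranks = {g: ranks[g] for g in genes}
    return StabilityTable("genorm", subset_name, values, ranks)


def genorm_pairwise_variation(
    q: QuantityMatrix, max_n: int, order: Sequence[str] | None = None
) -> pd.Series:
    """Pairwise variation V(n/n+1) of normalization factors.

    ``NF_n(s)`` is the geometric mean of the *n* most stable genes' quantities
    in sample *s*; ``V(n/n+1)`` is the SD over samples of
    ``log2(NF_n / NF_{n+1})``. The gene order is taken from
    :func:`genorm_ranking` unless supplied. V guides how many reference genes
    to use; the decision itself is left to the caller.
    """
    G = len(q.genes)
    if not 2 <= max_n < G:
        raise CtValidationError(f"max_n must satisfy 2 <= max_n < {G}, got {max_n}")
    if order is None:
        tbl = genorm_ranking(q)
        order = sorted(q.genes, key=lambda g: (tbl.ranks[g], q.genes.index(g)))
    else:
        if set(order) != set(q.genes):
            raise CtValidationError("order must be a permutation of the gene set")
    frame = q.frame()
    logq = np.log2(frame.loc[list(order)].to_numpy())
    out = {}
    for n in range(2, max_n + 1):
        nf_n = logq[:n].mean(axis=0)
        nf_n1 = logq[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, name="pairwise_variation")


# -- NormFinder ----------------------------------------------------------


def _nf_residual_variances(y: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variance estimates from a doubly-centered block.

    With the additive model y[g,s] = gene effect + sample effect + noise,
    double centering leaks a fraction of every gene's noise into every
    residual row; the correction below (G/(G-2) scaling minus a pooled term)
    makes the estimates unbiased. Estimates are floored at zero.
    """
    G, n = y.shape
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    ms = (r**2).sum(axis=1) / (n - 1)
    var = G / (G - 2) * (ms - ms.sum() / (G * (G - 1)))
    return np.maximum(var, 0.0)


def normfinder_stability(
    q: QuantityMatrix,
    groups: Mapping[str, str] | None = None,
    subset_name: str = "all",
) -> StabilityTable:
    """NormFinder stability values (SVs) on log2 quantities.

    Ungrouped: SV is the bias-corrected SD of a gene's doubly-centered
    residuals — its expression variance with the shared sample effect removed.

    Grouped: the intergroup bias d[g,j] (double-centered group means) is
    shrunk towards zero by its empirical-Bayes factor, and
    ``SV = mean over groups of |d~| + posterior SD of d``, combining
    systematic between-group differences with within-group noise.
    """
    G, S = q.q.shape
    if G < 3:
        raise CtValidationError("NormFinder needs at least 3 genes")
    y = np.log2(q.q)
    if groups is None:
        if S < 2:
            raise CtValidationError("NormFinder needs at least 2 samples")
        sv = np.sqrt(_nf_residual_variances(y))
        values = dict(zip(q.genes, sv.astype(float)))
        return StabilityTable.from_values("normfinder", subset_name, values)

    labels = []
    for s in q.samples:
        if s not in groups:
            raise CtValidationError(f"sample {s!r} has no group label")
        labels.append(groups[s])
    uniq = list(dict.fromkeys(labels))
    J = len(uniq)
    if J == 1:
        # one group: no intergroup component exists; the decomposition
        # reduces to the ungrouped analysis
        return normfinder_stability(q, None, subset_name)
    cols = {g: [i for i, lab in enumerate(labels) if lab == g] for g in uniq}
    sizes = {g: len(ix) for g, ix in cols.items()}
    singletons = [g for g, n in sizes.items() if n < 2]
    if singletons:
        raise CtValidationError(f"groups with fewer than 2 samples: {singletons}")

    var_gj = np.empty((G, J))
    mean_gj = np.empty((G, J))
    n_j = np.array([sizes[g] for g in uniq], dtype=float)
    for jx, lab in enumerate(uniq):
        block = y[:, cols[lab]]
        var_gj[:, jx] = _nf_residual_variances(block)
        mean_gj[:, jx] = block.mean(axis=1)
    d = (
        mean_gj
        - mean_gj.mean(axis=1, keepdims=True)
        - mean_gj.mean(axis=0, keepdims=True)
        + mean_gj.mean()
    )
    noise = var_gj / n_j[None, :]
    gamma2 = max(0.0, (d**2).sum() / ((G - 1) * (J - 1)) - noise.mean())
    denom = gamma2 + noise
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2 / denom, 0.0)
    d_shrunk = d * shrink
    post_var = noise * shrink  # Var(d | data) under the normal-normal model
    sv = (np.abs(d_shrunk) + np.sqrt(post_var)).mean(axis=1)
    values = dict(zip(q.genes, sv.astype(float)))
    return StabilityTable.from_values("normfinder", subset_name, values)


# -- BestKeeper ----------------------------------------------------------


@dataclass
class BestKeeperStats:
    """BestKeeper descriptive statistics.

    ``per_gene`` columns: ``sd_ct`` (cycles, about the arithmetic mean),
    ``cv_pct`` (100*SD/mean), ``geo_mean_ct``, ``r_vs_index`` (Pearson r of
    the gene's Ct against the index; NaN for a constant gene).
    ``index`` is the per-sample geometric mean of all genes' Ct.
    """

    subset_name: str
    per_gene: pd.DataFrame
    index: pd.Series


def bestkeeper_stats(m: CtMatrix, subset_name: str = "all") -> BestKeeperStats:
    """Descriptive BestKeeper statistics on raw (collapsed) Ct values."""
    x = _collapsed_complete(m, "bestkeeper_stats")
    G, S = x.shape
    if S < 2:
        raise CtValidationError("BestKeeper needs at least 2 samples")
    index = np.exp(np.log(x).mean(axis=0))
    rows = []
    for g, gene in enumerate(m.genes):
        sd = float(np.std(x[g], ddof=1))
        mean = float(np.mean(x[g]))
        geo = float(np.exp(np.log(x[g]).mean()))
        if sd == 0.0 or np.std(index) == 0.0:
            warnings.warn(
                f"gene {gene!r}: zero variance, correlation with index undefined",
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(sps.pearsonr(x[g], index).statistic)
        rows.append((sd, 100.0 * sd / mean, geo, r))
    per_gene = pd.DataFrame(
        rows,
        index=pd.Index(m.genes, name="gene"),
        columns=["sd_ct", "cv_pct", "geo_mean_ct", "r_vs_index"],
    )
    return BestKeeperStats(
        subset_name, per_gene, pd.Series(index, index=m.samples, name="bk_index")
    )


def bestkeeper_ranking(stats: BestKeeperStats, by: str = "sd") -> StabilityTable:
    """Rank genes by ascending Ct dispersion (``by='sd'`` default, or ``'cv'``)."""
    col = {"sd": "sd_ct", "cv": "cv_pct"}.get(by)
    if col is None:
        raise ValueError(f"by must be 'sd' or 'cv', got {by!r}")
    values = {g: float(v) for g, v in stats.per_gene[col].items()}
    return StabilityTable.from_values("bestkeeper", stats.subset_name, values)
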