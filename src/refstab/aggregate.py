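"""Consensus ranking of candidate reference genes.

Each stability method yields its own ordering; the consensus statistic is the
geometric mean of a gene's per-method competition ranks — a lower geometric
mean means a more stable gene. This is the plain unweighted aggregation rule
popularised by the RefFinder approach.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stability import StabilityTable

#: Fixed column order for four-method consensus tables.
METHOD_ORDER = ("delta_ct", "bestkeeper", "normfinder", "genorm")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 1.005 -> 1.01), as printed report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def competition_ranks(
    values: Mapping[str, float], lower_is_better: bool = True
) -> dict[str, int]:
    """Competition ("1224") ranks: ties share the minimum rank, the next
    distinct value skips by the tie count."""
    items = list(values.items())
    for gene, v in items:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing value for gene {gene!r}")
    keyed = sorted(items, key=lambda kv: kv[1] if lower_is_better else -kv[1])
    ranks: dict[str, int] = {}
    for pos, (gene, val) in enumerate(keyed):
        if pos > 0 and val == keyed[pos - 1][1]:
            ranks[gene] = ranks[keyed[pos - 1][0]]
        else:
            ranks[gene] = pos + 1
    return ranks


@dataclass
class ComprehensiveRanking:
    """Geometric-mean consensus over per-method ranks.

    ``geomean`` holds unrounded values (used for ordering); ``display`` the
    same values rounded half-up to two decimals, as consensus tables print
    them.
    """

    subset_name: str
    methods_used: list[str]
    rank_matrix: pd.DataFrame  # genes x methods, integer ranks
    geomean: dict[str, float]
    display: dict[str, float]
    final_rank: dict[str, int]

    def order(self) -> list[str]:
        """Genes from most to least stable (ascending geometric mean)."""
        return sorted(self.geomean, key=lambda g: (self.geomean[g], self.final_rank[g]))

    def to_frame(self) -> pd.DataFrame:
        df = self.rank_matrix.copy()
        df["geomean"] = [self.display[g] for g in df.index]
        df["final_rank"] = [self.final_rank[g] for g in df.index]
        return df.sort_values(["geomean", "final_rank"])


def geometric_mean_ranks(
    rank_matrix: pd.DataFrame, subset_name: str = "all"
) -> ComprehensiveRanking:
    """Aggregate a genes x methods matrix of integer ranks.

    The consensus value for gene *g* with ranks :math:`r_{g1},...,r_{gM}` is
    :math:`(\\prod_m r_{gm})^{1/M}`. Final ranks apply the competition rule to
    the unrounded geometric means.
    """
    if rank_matrix.shape[1] < 1:
        raise ValueError("at least one method is required")
    vals = rank_matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        missing = rank_matrix.index[np.isnan(vals).any(axis=1)].tolist()
        raise ValueError(f"genes missing a rank: {missing}")
    if (vals <= 0).any():
        raise ValueError("ranks must be positive integers")
    gm = np.exp(np.log(vals).mean(axis=1))
    geomean = dict(zip(rank_matrix.index, gm))
    return ComprehensiveRanking(
        subset_name=subset_name,
        methods_used=[str(c) for c in rank_matrix.columns],
        rank_matrix=rank_matrix.astype(int),
        geomean=geomean,
        display={g: round_half_up(v, 2) for g, v in geomean.items()},
        final_rank=competition_ranks(geomean),
    )


def comprehensive_report(
    tables: Sequence["StabilityTable"], subset_name: str | None = None
) -> ComprehensiveRanking:
    """Build the consensus ranking from per-method stability tables.

    Tables must share one gene set and one subset. Methods are arranged in the
    fixed order delta_ct, bestkeeper, normfinder, genorm (those present),
    followed by any extra methods in input order.
    """
    if not tables:
        raise ValueError("no stability tables supplied")
    subsets = {t.subset_name for t in tables}
    if subset_name is None:
        if len(subsets) > 1:
            raise ValueError(f"tables span multiple subsets: {sorted(subsets)}")
        subset_name = next(iter(subsets))
    gene_sets = [set(t.values) for t in tables]
    base = gene_sets[0]
    for t, gs in zip(tables, gene_sets):
        if gs != base:
            diff = sorted(base.symmetric_difference(gs))
            raise ValueError(
                f"gene sets differ between methods (table {t.method!r}): {diff}"
            )
    by_method = {t.method: t for t in tables}
    if len(by_method) != len(tables):
        raise ValueError("duplicate method among stability tables")
    ordered = [m for m in METHOD_ORDER if m in by_method]
    ordered += [t.method for t in tables if t.method not in ordered]
    genes = list(tables[0].values)
    rank_matrix = pd.DataFrame(
        {m: [by_method[m].ranks[g] for g in genes] for m in ordered},
        index=pd.Index(genes, name="gene"),
    )
    return geometric_mean_ranks(rank_matrix, subset_name)
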