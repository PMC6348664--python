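"""Standard-curve efficiency and multi-reference-gene normalization.

A dilution series gives Ct as a linear function of log10 template amount; the
slope yields the amplification efficiency ``E(%) = (10**(-1/slope) - 1) * 100``
(100% = perfect doubling per cycle). Target expression is the
efficiency-corrected relative quantity divided by a normalization factor — the
geometric mean of the reference genes' relative quantities in that sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ct_data import CtMatrix, CtValidationError
from .stability import to_relative_quantity

__all__ = [
    "StandardCurve",
    "NormalizedExpression",
    "fit_standard_curve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "normalization_factor",
    "relative_expression",
]


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from the dilution-curve slope."""
    if slope >= 0:
        raise ValueError(f"a valid dilution series has negative slope, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_pct: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    if efficiency_pct <= -100.0:
        raise ValueError("efficiency must exceed -100%")
    return -1.0 / math.log10(efficiency_pct / 100.0 + 1.0)


@dataclass
class StandardCurve:
    """Fitted dilution series: Ct = slope * log10(amount) + intercept.

    ``efficiency_pct`` is None when the fit is invalid (non-negative slope).
    """

    points: list[tuple[float, float]]  # (log10 amount, ct)
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float | None

    @property
    def valid(self) -> bool:
        return self.efficiency_pct is not None

    @property
    def amplification_factor(self) -> float:
        """Per-cycle factor E (2.0 = 100%), usable as a quantity-transform efficiency."""
        if not self.valid:
            raise ValueError("invalid curve has no amplification factor")
        return self.efficiency_pct / 100.0 + 1.0


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10 template amount.

    Requires at least three distinct dilution levels. A non-negative slope is
    returned as an invalid curve (``efficiency_pct=None``) rather than an
    error, so batch fits can proceed and flag failures.
    """
    pts = [(float(a), float(c)) for a, c in points]
    levels = {a for a, _ in pts}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct dilution levels, got {len(levels)}"
        )
    x = np.array([a for a, _ in pts])
    y = np.array([c for _, c in pts])
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    eff = efficiency_from_slope(slope) if slope < 0 else None
    return StandardCurve(pts, slope, float(fit.intercept), r2, eff)


def normalization_factor(
    m: CtMatrix,
    rg_set: Sequence[str],
    efficiencies: float | Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-sample normalization factor: geometric mean over the reference set
    of min-Ct-calibrated relative quantities."""
    rg = list(rg_set)
    if not rg:
        raise CtValidationError("reference-gene set is empty")
    missing = [g for g in rg if g not in m.genes]
    if missing:
        raise CtValidationError(f"reference genes absent from matrix: {missing}")
    q = to_relative_quantity(m, efficiencies)
    sub = q.frame().loc[rg]
    nf = np.exp(np.log(sub.to_numpy()).mean(axis=0))
    return pd.Series(nf, index=m.samples, name="nf")


@dataclass
class NormalizedExpression:
    """Target-gene expression normalized to a reference-gene set.

    ``table`` columns: ``mean`` and ``sd`` of normalized expression over
    biological replicates, per sample.
    """

    target_gene: str
    rg_set: list[str]
    table: pd.DataFrame
    per_replicate: pd.DataFrame  # samples x replicates normalized values


def relative_expression(
    target_ct: pd.DataFrame | pd.Series,
    nf: pd.Series,
    efficiency: float = 2.0,
    target_gene: str = "target",
    rg_set: Sequence[str] = (),
    calibrator: str | None = None,
) -> NormalizedExpression:
    """Efficiency-corrected target expression normalized by per-sample factors.

    ``target_ct`` is indexed by sample, with one column per biological
    replicate (a Series is treated as a single replicate). Each replicate's
    expression is ``efficiency ** (min_ct - ct) / nf[sample]``; the per-sample
    mean and SD over replicates are reported. With a ``calibrator`` sample the
    whole profile is rescaled so that sample's mean equals 1.
    """
    if isinstance(target_ct, pd.Series):
        target_ct = target_ct.to_frame("rep1")
    if efficiency <= 1.0:
        raise ValueError(f"amplification factor must exceed 1, got {efficiency}")
    extra = [s for s in target_ct.index if s not in nf.index]
    if extra:
        raise CtValidationError(f"samples missing a normalization factor: {extra}")
    ct = target_ct.to_numpy(dtype=float)
    min_ct = np.nanmin(ct)
    expr = efficiency ** (min_ct - ct) / nf.loc[target_ct.index].to_numpy()[:, None]
    per_rep = pd.DataFrame(expr, index=target_ct.index, columns=target_ct.columns)
    mean = np.nanmean(expr, axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(expr, axis=1, ddof=1) if expr.shape[1] > 1 else np.zeros(len(mean))
    if calibrator is not None:
        if calibrator not in target_ct.index:
            raise CtValidationError(f"calibrator sample {calibrator!r} not found")
        scale = mean[list(target_ct.index).index(calibrator)]
        mean, sd, per_rep = mean / scale, sd / scale, per_rep / scale
    table = pd.DataFrame(
        {"mean": mean, "sd": sd}, index=pd.Index(target_ct.index, name="sample")
    )
    return NormalizedExpression(target_gene, list(rg_set), table, per_rep)
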