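"""Bundled example data: the loquat candidate-reference-gene survey.

Three small tables ship with the package:

* :func:`load_rank_survey` — per-method stability ranks and the published
  geometric-mean consensus values for an 11-gene loquat candidate panel over
  five sample sets. The ``consistent`` flag marks cells whose printed
  per-method ranks reproduce the printed consensus value (one floral-subset
  cell carries a typographical rank inconsistency in the source table and is
  flagged 0).
* :func:`load_efficiencies` — dilution-series amplification efficiencies (%)
  and fit R^2 for the same panel's primer pairs.
* :func:`load_default_subsets` — the five default sample subsets of the
  23-sample tissue design used by the synthetic generator and the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .ct_data import SubsetSpec

__all__ = ["load_rank_survey", "load_efficiencies", "load_default_subsets"]

_DATA = resources.files(__package__) / "data"


def load_rank_survey() -> pd.DataFrame:
    """Columns: subset, gene, delta_ct, bestkeeper, normfinder, genorm
    (integer ranks), consensus (published 2-decimal geometric mean),
    consistent (bool)."""
    with (_DATA / "loquat_rank_survey.csv").open() as fh:
        df = pd.read_csv(fh)
    df["consistent"] = df["consistent"].astype(bool)
    return df


def load_efficiencies(as_factors: bool = False) -> pd.Series:
    """Per-gene amplification efficiency, in percent or as per-cycle factors
    (``as_factors=True``; 100% -> 2.0) ready for the quantity transform."""
    with (_DATA / "loquat_efficiencies.csv").open() as fh:
        df = pd.read_csv(fh, index_col="gene")
    eff = df["efficiency_pct"]
    return eff / 100.0 + 1.0 if as_factors else eff


def load_default_subsets() -> list[SubsetSpec]:
    with (_DATA / "default_subsets.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return [SubsetSpec(name, members) for name, members in raw.items()]
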