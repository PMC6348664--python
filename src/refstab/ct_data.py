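"""Ct-matrix data model and I/O.

The universal input of the pipeline is a matrix of quantification-cycle (Ct)
values with three axes: gene x sample x technical replicate. Missing wells are
carried as NaN and are never silently dropped; each downstream statistic
declares its own tolerance for them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class CtParseError(ValueError):
    """A Ct table file could not be parsed; the message names the offending cell."""


class CtValidationError(ValueError):
    """A Ct matrix or subset specification violates its contract."""


_LONG_COLUMNS = {"gene", "sample", "replicate", "ct"}
_WIDE_REP_RE = re.compile(r"^(?P<sample>.+)_(?P<rep>\d+)$")


@dataclass
class CtMatrix:
    """Gene x sample x replicate quantification cycles.

    Parameters
    ----------
    genes, samples
        Unique, ordered identifiers for the two leading axes.
    ct
        Array of shape ``(len(genes), len(samples), n_replicates)`` in cycles.
        ``NaN`` marks a missing well. Present values must be finite and > 0.
    groups
        Optional mapping from sample id to a group label (e.g. tissue type),
        used by the grouped NormFinder variant and by subset bookkeeping.
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    groups: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.ndim == 2:
            self.ct = self.ct[:, :, None]
        if self.ct.ndim != 3:
            raise CtValidationError(f"ct must be 3-dimensional, got ndim={self.ct.ndim}")
        if self.ct.shape[:2] != (len(self.genes), len(self.samples)):
            raise CtValidationError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.ct.shape[2] < 1:
            raise CtValidationError("at least one replicate is required")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise CtValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise CtValidationError(f"duplicate sample ids: {dupes}")
        present = self.ct[~np.isnan(self.ct)]
        if present.size and (not np.all(np.isfinite(present)) or np.any(present <= 0)):
            raise CtValidationError("all present Ct values must be finite and > 0")
        if self.groups is not None:
            unknown = sorted(set(self.groups) - set(self.samples))
            if unknown:
                raise CtValidationError(f"group labels for unknown samples: {unknown}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_replicates(self) -> int:
        return self.ct.shape[2]

    @property
    def is_collapsed(self) -> bool:
        return self.ct.shape[2] == 1

    def values2d(self) -> np.ndarray:
        """The gene x sample matrix of a replicate-collapsed dataset."""
        if not self.is_collapsed:
            raise CtValidationError(
                "matrix has uncollapsed replicates; call collapse_replicates first"
            )
        return self.ct[:, :, 0]

    def frame(self) -> pd.DataFrame:
        """Collapsed values as a genes x samples DataFrame."""
        return pd.DataFrame(self.values2d(), index=self.genes, columns=self.samples)

    def missing_cells(self) -> list[tuple[str, str, int]]:
        """(gene, sample, replicate) triples of missing wells."""
        gi, si, ri = np.nonzero(np.isnan(self.ct))
        return [(self.genes[g], self.samples[s], int(r) + 1) for g, s, r in zip(gi, si, ri)]

    def to_long(self) -> pd.DataFrame:
        recs = []
        for g, gene in enumerate(self.genes):
            for s, sample in enumerate(self.samples):
                for r in range(self.n_replicates):
                    recs.append((gene, sample, r + 1, self.ct[g, s, r]))
        df = pd.DataFrame(recs, columns=["gene", "sample", "replicate", "ct"])
        if self.groups is not None:
            df["group"] = df["sample"].map(self.groups)
        return df


@dataclass(frozen=True)
class SubsetSpec:
    """A named subset of samples (e.g. the fruit developmental series)."""

    name: str
    member_samples: tuple[str, ...]

    def __init__(self, name: str, member_samples: Iterable[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "member_samples", tuple(str(s) for s in member_samples))
        if not self.member_samples:
            raise CtValidationError(f"subset {self.name!r} is empty")

    def validate(self, m: CtMatrix) -> None:
        unknown = [s for s in self.member_samples if s not in m.samples]
        if unknown:
            raise CtValidationError(
                f"subset {self.name!r} names samples absent from the matrix: {unknown}"
            )


# -- I/O ----------------------------------------------------------------


def _parse_ct_cell(raw: object, where: str) -> float:
    if raw is None:
        return np.nan
    text = str(raw).strip()
    if text == "" or text.upper() in {"NA", "NAN", "N/A", "ND"}:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise CtParseError(f"non-numeric Ct value {text!r} at {where}") from None


def read_ct_table(
    path: str | Path,
    delimiter: str | None = None,
    groups: Mapping[str, str] | str | Path | None = None,
) -> CtMatrix:
    """Read a Ct matrix from delimited text.

    Two layouts are accepted and auto-detected:

    * **long** — columns ``gene, sample, replicate, ct`` (any case), with an
      optional ``group`` column;
    * **wide** — first column gene ids; remaining headers are either plain
      sample names (one replicate) or ``<sample>_<rep>`` pairs forming a
      complete, uniform replicate grid.

    Missing wells may be written as an empty cell or ``NA``.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.columns.size == 0:
        raise CtParseError(f"{path}: empty header line")
    lowered = [str(c).strip().lower() for c in df.columns]
    if _LONG_COLUMNS <= set(lowered):
        m = _from_long(df, lowered, path)
    else:
        m = _from_wide(df, path)
    if groups is not None:
        if isinstance(groups, (str, Path)):
            groups = read_groups(groups)
        m = CtMatrix(m.genes, m.samples, m.ct, dict(groups))
    return m


def _from_long(df: pd.DataFrame, lowered: list[str], path: Path) -> CtMatrix:
    df = df.rename(columns=dict(zip(df.columns, lowered)))
    genes = list(dict.fromkeys(df["gene"].astype(str)))
    samples = list(dict.fromkeys(df["sample"].astype(str)))
    try:
        reps = sorted({int(r) for r in df["replicate"]})
    except ValueError as exc:
        raise CtParseError(f"{path}: non-integer replicate index ({exc})") from None
    rep_pos = {r: i for i, r in enumerate(reps)}
    ct = np.full((len(genes), len(samples), len(reps)), np.nan)
    gpos = {g: i for i, g in enumerate(genes)}
    spos = {s: i for i, s in enumerate(samples)}
    seen: set[tuple[int, int, int]] = set()
    for row in df.itertuples(index=False):
        g, s, r = gpos[str(row.gene)], spos[str(row.sample)], rep_pos[int(row.replicate)]
        if (g, s, r) in seen:
            raise CtParseError(
                f"{path}: duplicate entry for gene {row.gene!r}, sample {row.sample!r}, "
                f"replicate {row.replicate}"
            )
        seen.add((g, s, r))
        ct[g, s, r] = _parse_ct_cell(row.ct, f"gene {row.gene!r}, sample {row.sample!r}")
    group_map = None
    if "group" in df.columns:
        group_map = {}
        for row in df.itertuples(index=False):
            val = getattr(row, "group", None)
            if val is not None and str(val) != "nan":
                group_map[str(row.sample)] = str(val)
    return CtMatrix(genes, samples, ct, group_map)


def _from_wide(df: pd.DataFrame, path: Path) -> CtMatrix:
    gene_col = df.columns[0]
    genes = [str(g) for g in df[gene_col]]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise CtValidationError(f"{path}: duplicate gene ids {dupes}")
    headers = [str(c) for c in df.columns[1:]]
    parsed = [_WIDE_REP_RE.match(h) for h in headers]
    if all(parsed) and len(headers) > 0:
        pairs = [(m["sample"], int(m["rep"])) for m in parsed]  # type: ignore[index]
        samples = list(dict.fromkeys(s for s, _ in pairs))
        reps = sorted({r for _, r in pairs})
        grid_ok = set(pairs) == {(s, r) for s in samples for r in reps}
    else:
        grid_ok = False
    if not grid_ok:
        samples, reps = headers, [1]
        pairs = [(h, 1) for h in headers]
    ct = np.full((len(genes), len(samples), len(reps)), np.nan)
    spos = {s: i for i, s in enumerate(samples)}
    rpos = {r: i for i, r in enumerate(reps)}
    for gi, gene in enumerate(genes):
        for (sample, rep), col in zip(pairs, headers):
            ct[gi, spos[sample], rpos[rep]] = _parse_ct_cell(
                df.iloc[gi][col], f"gene {gene!r}, column {col!r}"
            )
    return CtMatrix(genes, samples, ct)


def write_ct_table(m: CtMatrix, path: str | Path, layout: str = "long") -> None:
    """Write a Ct matrix as delimited text (``long`` or ``wide`` layout)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    if layout == "long":
        m.to_long().to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        cols = {}
        for s, sample in enumerate(m.samples):
            for r in range(m.n_replicates):
                name = sample if m.is_collapsed else f"{sample}_{r + 1}"
                cols[name] = m.ct[:, s, r]
        pd.DataFrame(cols, index=pd.Index(m.genes, name="gene")).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample -> group mapping from a YAML/JSON-style key-value file.

    Accepts either ``sample: group`` pairs or ``group: [samples...]`` lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CtParseError(f"{path}: expected a mapping")
    out: dict[str, str] = {}
    for key, val in raw.items():
        if isinstance(val, (list, tuple)):
            for sample in val:
                out[str(sample)] = str(key)
        else:
            out[str(key)] = str(val)
    return out


def read_subsets(path: str | Path) -> list[SubsetSpec]:
    """Read named sample subsets from a ``name: [samples...]`` mapping file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CtParseError(f"{path}: expected a mapping of subset name -> sample list")
    return [SubsetSpec(name, members) for name, members in raw.items()]


# -- transformations ----------------------------------------------------


def collapse_replicates(m: CtMatrix, how: str = "mean") -> CtMatrix:
    """Collapse the replicate axis to length 1 by mean or median of present wells.

    A cell whose replicates are all missing stays missing; such cells are
    reported in a single warning.
    """
    if how not in {"mean", "median"}:
        raise ValueError(f"how must be 'mean' or 'median', got {how!r}")
    if m.is_collapsed:
        return CtMatrix(list(m.genes), list(m.samples), m.ct.copy(), m.groups)
    reducer = np.nanmean if how == "mean" else np.nanmedian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        collapsed = reducer(m.ct, axis=2)
    empty = np.isnan(collapsed) & np.isnan(m.ct).all(axis=2)
    if empty.any():
        cells = [
            (m.genes[g], m.samples[s]) for g, s in zip(*np.nonzero(empty))
        ]
        warnings.warn(
            f"all replicates missing for cells {cells}; left missing", stacklevel=2
        )
    return CtMatrix(list(m.genes), list(m.samples), collapsed[:, :, None], m.groups)


def subset_samples(m: CtMatrix, spec: SubsetSpec) -> CtMatrix:
    """Project the matrix onto the samples of ``spec``, in spec order."""
    spec.validate(m)
    idx = [m.samples.index(s) for s in spec.member_samples]
    groups = None
    if m.groups is not None:
        groups = {s: m.groups[s] for s in spec.member_samples if s in m.groups}
    return CtMatrix(list(m.genes), list(spec.member_samples), m.ct[:, idx, :], groups)


def summarize_expression(m: CtMatrix) -> pd.DataFrame:
    """Five-number summary of collapsed Ct per gene over samples.

    Returns a DataFrame indexed by gene with columns
    ``min, q1, median, q3, max, n`` — the numbers a boxplot of expression
    levels displays. Missing cells are ignored; a gene with zero observations
    is an error.
    """
    x = m.values2d()
    rows = []
    for g, gene in enumerate(m.genes):
        vals = x[g][~np.isnan(x[g])]
        if vals.size == 0:
            raise CtValidationError(f"gene {gene!r} has no observed Ct values")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((vals.min(), q1, med, q3, vals.max(), vals.size))
    return pd.DataFrame(
        rows,
        index=pd.Index(m.genes, name="gene"),
        columns=["min", "q1", "median", "q3", "max", "n"],
    )
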