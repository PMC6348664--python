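"""End-to-end stability pipeline: Ct table in, ranked report bundle out.

For each configured sample subset the pipeline runs the four stability
methods, aggregates them into the geometric-mean consensus, and writes both
machine-readable (long CSV) and human-readable ("value (rank)" grid) reports.
Every defaulted analysis switch is recorded in the run log, because different
defaults (replicate collapse, efficiency source, NormFinder grouping) change
the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .aggregate import ComprehensiveRanking, comprehensive_report
from .ct_data import (
    CtMatrix,
    CtValidationError,
    SubsetSpec,
    collapse_replicates,
    read_ct_table,
    subset_samples,
    summarize_expression,
)
from .datasets import load_default_subsets, load_efficiencies
from .stability import (
    StabilityTable,
    bestkeeper_ranking,
    bestkeeper_stats,
    delta_ct_stability,
    genorm_ranking,
    normfinder_stability,
    to_relative_quantity,
)

__all__ = ["PipelineConfig", "SubsetResult", "run_pipeline", "read_stability_long"]


@dataclass
class PipelineConfig:
    """Switches of one pipeline run; every default is logged."""

    input_path: str | Path | None = None
    matrix: CtMatrix | None = None
    subsets: Sequence[SubsetSpec] | None = None  # None -> bundled defaults
    groups: Mapping[str, str] | None = None
    collapse: str = "mean"
    efficiencies: float | Mapping[str, float] | str | None = None  # None -> 2.0, "panel" -> bundled
    normfinder_grouped: bool = False
    bestkeeper_by: str = "sd"
    outdir: str | Path | None = None

    def resolve_matrix(self) -> CtMatrix:
        if self.matrix is not None:
            return self.matrix
        if self.input_path is None:
            raise CtValidationError("either input_path or matrix must be given")
        return read_ct_table(self.input_path, groups=self.groups)

    def resolve_efficiencies(self) -> tuple[float | Mapping[str, float] | None, str]:
        if self.efficiencies is None:
            return None, "default factor 2.0 (100%) for all genes"
        if isinstance(self.efficiencies, str):
            if self.efficiencies == "panel":
                return load_efficiencies(as_factors=True).to_dict(), "bundled panel standard-curve efficiencies"
            df = pd.read_csv(self.efficiencies, index_col=0)
            col = df.columns[0]
            vals = df[col]
            factors = vals / 100.0 + 1.0 if col.endswith("pct") else vals
            return factors.to_dict(), f"file {self.efficiencies} (column {col})"
        return self.efficiencies, "user-supplied efficiencies"


@dataclass
class SubsetResult:
    subset: SubsetSpec
    tables: dict[str, StabilityTable]
    comprehensive: ComprehensiveRanking
    summary: pd.DataFrame


def _table2_grid(result: SubsetResult) -> str:
    genes = list(result.tables["delta_ct"].values)
    lines = ["\t".join(["method"] + genes)]
    for method in ("delta_ct", "bestkeeper", "normfinder", "genorm"):
        t = result.tables[method]
        cells = [f"{t.values[g]:.2f} ({t.ranks[g]})" for g in genes]
        lines.append("\t".join([method] + cells))
    comp = result.comprehensive
    cells = [f"{comp.display[g]:.2f} ({comp.final_rank[g]})" for g in genes]
    lines.append("\t".join(["comprehensive"] + cells))
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict[str, SubsetResult]:
    """Run the full evaluation; returns per-subset results keyed by subset name.

    When ``config.outdir`` is set, writes per subset a long-format stability
    table, the consensus table, and a "value (rank)" grid, plus a run log and
    an expression summary of the full collapsed matrix.
    """
    m = config.resolve_matrix()
    if config.groups is not None and m.groups is None:
        m = CtMatrix(m.genes, m.samples, m.ct, dict(config.groups))
    collapsed = collapse_replicates(m, config.collapse)
    subsets = list(config.subsets) if config.subsets is not None else load_default_subsets()
    eff, eff_desc = config.resolve_efficiencies()

    log_lines = [
        f"replicate collapse: {config.collapse}",
        f"efficiencies: {eff_desc}",
        f"normfinder grouping: {'grouped' if config.normfinder_grouped else 'ungrouped'}",
        f"bestkeeper criterion: {config.bestkeeper_by}",
        f"subsets: {', '.join(s.name for s in subsets)}",
    ]

    results: dict[str, SubsetResult] = {}
    for spec in subsets:
        sub = subset_samples(collapsed, spec)
        q = to_relative_quantity(sub, eff)
        groups = sub.groups if config.normfinder_grouped else None
        if config.normfinder_grouped and not groups:
            raise CtValidationError(
                f"subset {spec.name!r}: grouped NormFinder requested but no group labels"
            )
        tables = {
            "delta_ct": delta_ct_stability(sub, spec.name),
            "bestkeeper": bestkeeper_ranking(
                bestkeeper_stats(sub, spec.name), config.bestkeeper_by
            ),
            "normfinder": normfinder_stability(q, groups, spec.name),
            "genorm": genorm_ranking(q, spec.name),
        }
        comp = comprehensive_report(list(tables.values()))
        results[spec.name] = SubsetResult(spec, tables, comp, summarize_expression(sub))

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        summarize_expression(collapsed).to_csv(outdir / "expression_summary.csv")
        for name, res in results.items():
            d = outdir / name.replace(" ", "_")
            d.mkdir(exist_ok=True)
            long = pd.concat([t.to_frame() for t in res.tables.values()])
            long.to_csv(d / "stability_long.csv", index=False)
            res.comprehensive.to_frame().to_csv(d / "comprehensive.csv")
            (d / "report.txt").write_text(_table2_grid(res))
    return results


def read_stability_long(path: str | Path) -> list[StabilityTable]:
    """Re-read a written ``stability_long.csv`` into StabilityTable objects."""
    df = pd.read_csv(path)
    out = []
    for (method, subset), grp in df.groupby(["method", "subset"], sort=False):
        out.append(
            StabilityTable(
                str(method),
                str(subset),
                dict(zip(grp["gene"].astype(str), grp["value"].astype(float))),
                dict(zip(grp["gene"].astype(str), grp["rank"].astype(int))),
            )
        )
    return out
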