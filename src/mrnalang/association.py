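"""Group-wise linear regression of sequence parameters against ln(kf).

Each of the 12 per-sequence statistics is regressed on the natural log of
the protein folding rate, first over all proteins, then within kinetic
classes (two-state / multistate), and the whole analysis is repeated
within each structural class (all-α, all-β, α-β).  The reported quantity
is the signed Pearson correlation coefficient with a two-sided p-value
from the t statistic r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom;
slope and intercept of the least-squares line are carried along.

Significance stars use the conventional 0.05 / 0.01 / 0.001 levels
(configurable).  No multiple-testing correction is applied by default
across the 12-parameter grid; a Benjamini–Hochberg adjustment is available
as a clearly separate option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    EmptyDatasetError,
    ShapeError,
)
from .sequence_io import (
    KineticClass,
    PARAMETER_COLUMNS,
    StructuralClass,
    StudyDataset,
)

#: (p < 0.001, p < 0.01, p < 0.05) -> "***", "**", "*"
DEFAULT_STAR_THRESHOLDS = (0.001, 0.01, 0.05)

#: Row order of every correlation table.
GROUP_ROWS = ("all", "two_state", "multi_state")

#: Table order: pooled table first, then one per structural class.
TABLE_KEYS = ("all_proteins", "all_alpha", "all_beta", "alpha_beta")

#: Token used for cells that cannot be computed (n < 3 or constant input).
NOT_COMPUTABLE = "NC"


def stars(p_value: float, thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS) -> str:
    """Map a p-value to its significance marker ('***', '**', '*' or '')."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    t3, t2, t1 = thresholds
    if p_value < t3:
        return "***"
    if p_value < t2:
        return "**"
    if p_value < t1:
        return "*"
    return ""


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DegenerateInputError(f"need n >= 3, got n = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.pvalue)


@dataclass(frozen=True)
class AssociationResult:
    """Correlation/regression summary for one (group, parameter) pair."""

    group: str
    parameter: str
    n: int
    r: float | None = None
    slope: float | None = None
    intercept: float | None = None
    p_value: float | None = None
    stars: str = ""
    computable: bool = True
    reason: str = ""

    def formatted(self) -> str:
        """Cell text in the published style: r to two decimals plus stars."""
        if not self.computable:
            return NOT_COMPUTABLE
        return f"{self.r:.2f}{self.stars}"


@dataclass(frozen=True)
class CorrelationTable:
    """Groups × 12-parameter grid of association results."""

    name: str
    rows: tuple[str, ...]
    columns: tuple[str, ...]
    cells: Mapping[tuple[str, str], AssociationResult]

    def __post_init__(self) -> None:
        for row in self.rows:
            for col in self.columns:
                if (row, col) not in self.cells:
                    raise EmptyDatasetError(
                        f"table {self.name}: missing cell ({row}, {col})"
                    )

    def cell(self, row: str, column: str) -> AssociationResult:
        return self.cells[(row, column)]

    def to_frame(self) -> pd.DataFrame:
        """Human-readable frame: two-decimal r with stars, NC where undefined."""
        data = {
            col: [self.cells[(row, col)].formatted() for row in self.rows]
            for col in self.columns
        }
        return pd.DataFrame(data, index=list(self.rows))

    def to_long_frame(self) -> pd.DataFrame:
        """Full-precision long format: one row per (group, parameter)."""
        recs = []
        for row in self.rows:
            for col in self.columns:
                c = self.cells[(row, col)]
                recs.append(
                    {
                        "table": self.name,
                        "group": c.group,
                        "parameter": c.parameter,
                        "n": c.n,
                        "r": c.r,
                        "slope": c.slope,
                        "intercept": c.intercept,
                        "p_value": c.p_value,
                        "stars": c.stars,
                        "computable": c.computable,
                        "reason": c.reason,
                    }
                )
        return pd.DataFrame(recs)


def associate(
    x: Sequence[float],
    y: Sequence[float],
    group: str,
    parameter: str,
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
) -> AssociationResult:
    """One cell: Pearson r, regression line and significance for x vs y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = int(x.size)
    try:
        if x.shape != y.shape:
            raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
        if n < 3:
            raise DegenerateInputError(f"need n >= 3, got n = {n}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateInputError("constant input vector")
    except (DegenerateInputError, ShapeError) as exc:
        return AssociationResult(
            group=group, parameter=parameter, n=n,
            computable=False, reason=str(exc),
        )
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    return AssociationResult(
        group=group,
        parameter=parameter,
        n=n,
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        stars=stars(p, star_thresholds),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional extension; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def _table_for(
    records,
    params_by_id: Mapping[str, Mapping[str, float]],
    name: str,
    star_thresholds: Sequence[float],
) -> CorrelationTable:
    groups = {
        "all": list(records),
        "two_state": [r for r in records if r.kinetic_class is KineticClass.TWO_STATE],
        "multi_state": [r for r in records if r.kinetic_class is KineticClass.MULTI_STATE],
    }
    cells: dict[tuple[str, str], AssociationResult] = {}
    for row, recs in groups.items():
        y = np.array([r.ln_kf for r in recs])
        for col in PARAMETER_COLUMNS:
            x = np.array([params_by_id[r.id][col] for r in recs])
            cells[(row, col)] = associate(x, y, row, col, star_thresholds)
    return CorrelationTable(
        name=name, rows=GROUP_ROWS, columns=PARAMETER_COLUMNS, cells=cells
    )


def build_tables(
    dataset: StudyDataset,
    params: pd.DataFrame,
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
) -> dict[str, CorrelationTable]:
    """Build the four correlation tables from a dataset and its parameters.

    ``params`` is the per-protein table from
    :func:`mrnalang.infostats.compute_parameter_table` (columns id + the 12
    parameter names).  Returns the pooled table plus one per structural
    class, each with rows all / two_state / multi_state.  Cells whose group
    has fewer than 3 members, or a constant parameter, are flagged
    not-computable rather than dropped.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("dataset has no records")
    missing = set(dataset.ids) - set(params["id"])
    if missing:
        raise EmptyDatasetError(f"records without parameter rows: {sorted(missing)}")
    params_by_id = {
        row["id"]: {c: row[c] for c in PARAMETER_COLUMNS}
        for _, row in params.iterrows()
    }
    tables = {
        "all_proteins": _table_for(
            dataset.records, params_by_id, "all_proteins", star_thresholds
        )
    }
    for sc in StructuralClass:
        recs = [r for r in dataset if r.structural_class is sc]
        tables[sc.value] = _table_for(recs, params_by_id, sc.value, star_thresholds)
    return tables


def write_tables(tables: Mapping[str, CorrelationTable], outdir: str | Path) -> list[Path]:
    """Write the formatted tables plus one long-format full-precision file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    long_frames = []
    for key in TABLE_KEYS:
        table = tables[key]
        path = outdir / f"correlations_{key}.csv"
        table.to_frame().to_csv(path, index_label="group")
        written.append(path)
        long_frames.append(table.to_long_frame())
    long_path = outdir / "correlations_long.csv"
    pd.concat(long_frames, ignore_index=True).to_csv(
        long_path, index=False, float_format="%.12g"
    )
    written.append(long_path)
    return written
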