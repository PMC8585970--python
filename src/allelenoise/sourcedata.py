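"""Figure-wise X,Y workbook reader and the published-contrast recomputation.

The study's deposited workbook stores, per figure, the paired allele
expression values (X, Y) for each cell of each group.  Its exact sheet and
column naming is not standardized, so the reader is layout-configurable;
the default layout matches the workbooks this package writes itself (one
sheet per figure key, columns group / experiment / x / y, optionally a
precomputed noise column for cross-checking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._exceptions import ParameterError
from .noise import (
    normalize_per_experiment,
    per_cell_intrinsic_noise,
    percent_decrease,
    summarize_noise,
)

#: figure keys with a two-group introns-vs-intronless contrast
FIGURE_KEYS = ("fig2ab", "fig2cd", "fig2ef", "fig4ab", "fig4cd", "fig4ef", "fig4gh", "fig7ab")


@dataclass
class SourceDataLayout:
    """Mapping from figure keys to sheet names and column labels."""

    sheet_map: dict = field(default_factory=lambda: {k: k for k in FIGURE_KEYS})
    group_col: str = "group"
    experiment_col: str = "experiment"
    x_col: str = "x"
    y_col: str = "y"
    noise_col: str = "noise"  # optional; cross-checked when present
    reference_group: str = "intronless"
    treated_group: str = "introns"


def write_source_data_workbook(path, sheets: dict[str, pd.DataFrame],
                               layout: SourceDataLayout | None = None) -> None:
    """Write per-figure X,Y tables to an Excel workbook (one sheet each).

    Input frames use the measurement-table layout (group_label,
    experiment_id, x, y); columns are renamed to the workbook layout.
    """
    layout = layout or SourceDataLayout()
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for key, df in sheets.items():
            out = pd.DataFrame(
                {
                    layout.group_col: df["group_label"],
                    layout.experiment_col: df["experiment_id"],
                    layout.x_col: df["x"],
                    layout.y_col: df["y"],
                }
            )
            out.to_excel(xl, sheet_name=layout.sheet_map.get(key, key), index=False)


def read_figure_sheet(path, figure_key: str,
                      layout: SourceDataLayout | None = None) -> pd.DataFrame:
    """Read one figure's X,Y table into the measurement-table layout."""
    layout = layout or SourceDataLayout()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: the figure-wise X,Y workbook is an optional external "
            "input and is not bundled; point to a downloaded copy"
        )
    if figure_key not in layout.sheet_map:
        raise ParameterError(
            f"unknown figure_key {figure_key!r}; known: {sorted(layout.sheet_map)}"
        )
    raw = pd.read_excel(path, sheet_name=layout.sheet_map[figure_key])
    for col in (layout.group_col, layout.experiment_col, layout.x_col, layout.y_col):
        if col not in raw.columns:
            raise ParameterError(f"sheet lacks required column {col!r}")
    df = pd.DataFrame(
        {
            "cell_id": [f"r{i + 1:05d}" for i in range(len(raw))],
            "experiment_id": raw[layout.experiment_col].astype(str),
            "group_label": raw[layout.group_col].astype(str),
            "tissue": "unknown",
            "x": raw[layout.x_col].astype(float),
            "y": raw[layout.y_col].astype(float),
        }
    )
    if layout.noise_col in raw.columns:
        df["published_noise"] = raw[layout.noise_col].astype(float)
    return df


def reproduce_published(source_data_path, figure_key: str,
                        layout: SourceDataLayout | None = None) -> dict:
    """Recompute a figure's percent decrease in median intrinsic noise.

    Reads the figure's X,Y columns, applies per-experiment normalization,
    per-cell intrinsic noise and the percentile summary for both groups,
    and returns the percent decrease of the treated (introns) group's
    median relative to the reference (intronless) group, plus a comparison
    against the workbook's own noise column when present.
    """
    layout = layout or SourceDataLayout()
    df = read_figure_sheet(source_data_path, figure_key, layout)
    norm = normalize_per_experiment(df)
    report: dict = {"figure_key": figure_key, "groups": {}}
    medians = {}
    for grp in (layout.reference_group, layout.treated_group):
        pc = per_cell_intrinsic_noise(norm, grp)
        summ = summarize_noise(pc["intrinsic_noise"])
        medians[grp] = summ.median
        report["groups"][grp] = summ.to_dict()
        if "published_noise" in norm.columns:
            pub = norm.loc[norm["group_label"] == grp, "published_noise"]
            diff = (pc["intrinsic_noise"].to_numpy() - pub.to_numpy())
            report["groups"][grp]["max_abs_diff_vs_published"] = float(
                abs(diff).max()
            )
    report["percent_decrease"] = percent_decrease(
        medians[layout.reference_group], medians[layout.treated_group]
    )
    return report
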