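"""Per-experiment normalization and dual-reporter intrinsic-noise statistics.

The central statistic quantifies stochastic allele bias per cell as

    intrinsic noise = (x − y)² / (2⟨x⟩⟨y⟩)

where x and y are the cell's two allele intensities (after each has been
divided by its experiment mean) and ⟨x⟩, ⟨y⟩ are the allele means over all
cells of the group.  Cells on the 1:1 diagonal score 0; a fully monoallelic
cell scores high.  The population decomposition splits squared noise into
an uncorrelated (intrinsic) and a correlated (extrinsic) component:

    intrinsic² = ⟨(x−y)²⟩ / (2⟨x⟩⟨y⟩)
    extrinsic² = (⟨xy⟩ − ⟨x⟩⟨y⟩) / (⟨x⟩⟨y⟩)
    total²     = intrinsic² + extrinsic²

and the mean of the per-cell values equals intrinsic² exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateInputError, EmptyGroupError, ParameterError


def normalize_per_experiment(dataset: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's x and y by its experiment's mean x and mean y.

    Channel gains and 8-bit/16-bit acquisition differences cancel here:
    rescaling either channel within an experiment by any positive constant
    leaves the normalized data unchanged.  Every experiment must have at
    least 2 cells and positive means in both channels.
    """
    for col in ("experiment_id", "x", "y"):
        if col not in dataset.columns:
            raise ParameterError(f"dataset is missing required column {col!r}")
    out = dataset.copy()
    for exp_id, idx in dataset.groupby("experiment_id").groups.items():
        sub = dataset.loc[idx]
        if len(sub) < 2:
            raise DegenerateInputError(
                f"experiment {exp_id!r} has fewer than 2 cells"
            )
        mx, my = sub["x"].mean(), sub["y"].mean()
        if mx <= 0 or my <= 0:
            raise DegenerateInputError(
                f"experiment {exp_id!r} has nonpositive mean expression"
            )
        out.loc[idx, "x"] = sub["x"] / mx
        out.loc[idx, "y"] = sub["y"] / my
    return out


def per_cell_intrinsic_noise(
    dataset: pd.DataFrame, group: str, means: str = "pooled"
) -> pd.DataFrame:
    """Per-cell intrinsic noise (x−y)²/(2⟨x⟩⟨y⟩) for one group.

    ``means`` selects how ⟨x⟩, ⟨y⟩ are taken on the normalized data:
    ``"pooled"`` (default) over all cells of the group across experiments —
    matching how per-cell values from several experiments land in a single
    boxplot — or ``"per_experiment"``, in which case the means are 1 by
    construction and the statistic reduces to (x−y)²/2 per experiment.

    Cells with x = y = 0 get noise 0 (the formula's numerator limit) and
    are flagged in the ``zero_pair`` column.
    """
    if means not in ("pooled", "per_experiment"):
        raise ParameterError("means must be 'pooled' or 'per_experiment'")
    sub = dataset[dataset["group_label"] == group]
    if len(sub) == 0:
        raise EmptyGroupError(f"group {group!r} has no cells")
    x = sub["x"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    if means == "pooled":
        mx, my = x.mean(), y.mean()
        if mx <= 0 or my <= 0:
            raise DegenerateInputError(f"group {group!r} has nonpositive mean")
        noise = (x - y) ** 2 / (2.0 * mx * my)
    else:
        noise = np.empty(len(sub))
        for _, idx in sub.groupby("experiment_id").groups.items():
            pos = sub.index.get_indexer(idx)
            mx, my = x[pos].mean(), y[pos].mean()
            if mx <= 0 or my <= 0:
                raise DegenerateInputError("experiment with nonpositive mean")
            noise[pos] = (x[pos] - y[pos]) ** 2 / (2.0 * mx * my)
    zero_pair = (x == 0) & (y == 0)
    noise[zero_pair] = 0.0
    return pd.DataFrame(
        {
            "cell_id": sub["cell_id"].to_numpy(),
            "experiment_id": sub["experiment_id"].to_numpy(),
            "group_label": group,
            "intrinsic_noise": noise,
            "zero_pair": zero_pair,
        }
    )


def population_noise_decomposition(
    dataset: pd.DataFrame, group: str
) -> tuple[float, float, float]:
    """(intrinsic², extrinsic², total²) for one group of normalized cells."""
    sub = dataset[dataset["group_label"] == group]
    if len(sub) == 0:
        raise EmptyGroupError(f"group {group!r} has no cells")
    x = sub["x"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    mx, my = x.mean(), y.mean()
    if mx <= 0 or my <= 0:
        raise DegenerateInputError(f"group {group!r} has nonpositive mean")
    intrinsic2 = np.mean((x - y) ** 2) / (2.0 * mx * my)
    extrinsic2 = (np.mean(x * y) - mx * my) / (mx * my)
    return float(intrinsic2), float(extrinsic2), float(intrinsic2 + extrinsic2)


def spearman_r2(xs, ys) -> float:
    """Squared Spearman rank correlation (coefficient of determination)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ParameterError("need >= 3 paired values")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise DegenerateInputError("rank correlation undefined for constant input")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho**2)


@dataclass
class NoiseSummary:
    """Boxplot-convention summary: median, quartiles, 10/90 and 5/95 tails."""

    n: int
    mean: float
    median: float
    q25: float
    q75: float
    p10: float
    p90: float
    p5: float
    p95: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_noise(values) -> NoiseSummary:
    """Percentile summary (linear interpolation between order statistics)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyGroupError("cannot summarize an empty set of values")
    pct = np.percentile(v, [5, 10, 25, 50, 75, 90, 95])
    return NoiseSummary(
        n=int(v.size),
        mean=float(v.mean()),
        median=float(pct[3]),
        q25=float(pct[2]),
        q75=float(pct[4]),
        p10=float(pct[1]),
        p90=float(pct[5]),
        p5=float(pct[0]),
        p95=float(pct[6]),
    )


def percent_decrease(reference_median: float, treated_median: float) -> float:
    """100·(1 − treated/reference): the headline effect-size convention."""
    if reference_median <= 0:
        raise DegenerateInputError("reference_median must be > 0")
    return 100.0 * (1.0 - treated_median / reference_median)
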