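"""Cumulative-fit matrices and plots for fitted logistic models.

The fit matrix decomposes each sample's linear predictor into one column
per model term: entry (i, j) = x_ij * beta_j, with a constant intercept
column. Accumulating the columns in ascending effect-size order (intercept
folded into the first column) and mapping each running sum through the
logistic function yields, per sample, a path of predicted probabilities
that ends exactly at the model's predicted probability — the cumulative
fit plot draws one such path per sample, colored by outcome group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cantare.models import LogisticFit

logger = logging.getLogger(__name__)


@dataclass
class CumulativeFitMatrix:
    """Per-sample cumulative predictor contributions, both scales.

    Columns are ordered by ascending effect size with the intercept folded
    into the first column; ``log_odds[:, j]`` is the running sum of term
    contributions through column j and ``probability`` its logistic
    transform. The final probability column equals the model's predicted
    probabilities.
    """

    log_odds: pd.DataFrame
    probability: pd.DataFrame
    group: np.ndarray

    @property
    def predictor_order(self) -> list[str]:
        return list(self.log_odds.columns)


def fit_matrix(model: LogisticFit, data: pd.DataFrame) -> pd.DataFrame:
    """Per-term contributions to the linear predictor: (i, j) -> x_ij * beta_j.

    The 'intercept' column is constant at beta_0; row sums equal the
    model's linear predictor.
    """
    missing = [p for p in model.predictors if p not in data.columns]
    if missing:
        raise KeyError(f"data lacks predictor column(s) {missing}")
    out = pd.DataFrame(index=data.index)
    out["intercept"] = model.params["intercept"]
    for name in model.predictors:
        out[name] = data[name].to_numpy(dtype=float) * model.params[name]
    return out


def cumulative_fit(
    contributions: pd.DataFrame,
    effect_size_order: Sequence[str],
    group: np.ndarray | None = None,
) -> CumulativeFitMatrix:
    """Accumulate contribution columns in effect-size order.

    Column 1 is the intercept plus the smallest-effect term; column j is
    the running sum through the j-th term; probabilities are
    1 / (1 + exp(-z)). The accumulation order changes intermediate columns
    only — the final column is the full linear predictor regardless.
    """
    order = list(effect_size_order)
    unknown = [c for c in order if c not in contributions.columns]
    if unknown:
        raise KeyError(f"effect-size order references unknown column(s) {unknown}")
    non_intercept = [c for c in contributions.columns if c != "intercept"]
    if set(order) != set(non_intercept):
        raise ValueError("effect-size order must cover all non-intercept columns")
    cum = pd.DataFrame(index=contributions.index)
    running = contributions["intercept"].to_numpy(dtype=float).copy()
    for name in order:
        running = running + contributions[name].to_numpy(dtype=float)
        cum[name] = running
    prob = 1.0 / (1.0 + np.exp(-cum))
    if group is None:
        group = np.zeros(len(contributions), dtype=int)
    return CumulativeFitMatrix(
        log_odds=cum, probability=prob, group=np.asarray(group)
    )


GROUP_COLORS = {0: "#2ca02c", 1: "#ff7f0e"}  # control green, case orange


def plot_cumulative(
    matrix: CumulativeFitMatrix,
    out_path: str | Path,
    title: str = "",
) -> Path:
    """Render the cumulative-fit plot (one probability path per sample).

    Paths are colored by group, a dotted trend line connects the mean
    cumulative log-odds (transformed to probability) at each column, and a
    thick vertical marker at the final column indicates the cumulative
    predicted probability. Output is deterministic for fixed input.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if matrix.probability.shape[0] < 1:
        raise ValueError("need at least one sample to plot")
    levels = np.unique(matrix.group)
    if len(levels) < 2:
        logger.warning("single-group input: rendering with one color")

    cols = matrix.predictor_order
    xs = np.arange(1, len(cols) + 1)
    fig, ax = plt.subplots(figsize=(max(6.0, 0.9 * len(cols)), 4.5))
    for i in range(matrix.probability.shape[0]):
        g = int(matrix.group[i])
        ax.plot(
            xs,
            matrix.probability.iloc[i].to_numpy(),
            color=GROUP_COLORS.get(g, "#555555"),
            alpha=0.45,
            linewidth=0.9,
        )
    # trend line: mean on the accumulation (log-odds) scale, then transformed
    mean_lo = matrix.log_odds.mean(axis=0).to_numpy()
    ax.plot(xs, 1.0 / (1.0 + np.exp(-mean_lo)), "k:", linewidth=1.8, label="trend")
    ax.axvline(xs[-1], color="black", linewidth=3.0)
    ax.set_xticks(xs)
    ax.set_xticklabels(cols, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("cumulative predicted probability")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path = Path(out_path)
    metadata = {"Date": None} if out_path.suffix.lower() == ".svg" else None
    with matplotlib.rc_context({"svg.hashsalt": "cantare"}):
        fig.savefig(out_path, metadata=metadata)
    plt.close(fig)
    return out_path
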