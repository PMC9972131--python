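"""Back-solve the two-normal example parameters from the published table.

The worked single-index example fixes a human class standardized to
N(0, 1) but never prints the bot class parameters.  This script grid
searches over (bot mean, bot sd), scoring each candidate by the maximum
absolute deviation (in percentage points) from the 20 published accuracy
cells plus the published 96.1% ROC area, and prints the minimizer.  The
solved values are shipped as ``TWO_NORMAL_EXAMPLE_PARAMS`` in
``scump.metrics_theory``.

Run:  python scripts/solve_two_normal.py
"""

from __future__ import annotations

import numpy as np

from scump.metrics_theory import (
    TABLE1_CONTAMINATION_ROWS,
    TABLE1_SPECIFICITY_COLS,
    TwoNormalNRI,
    theory_accuracy_table,
    two_normal_auc,
)

# Published accuracy cells (percent): rows = contamination 5/25/50/75/95%,
# columns = specificity 85/90/95/99%.
PUBLISHED_TABLE = np.array([
    [85.4, 89.9, 94.3, 96.9],
    [87.0, 89.7, 91.3, 88.5],
    [88.9, 89.4, 87.7, 77.9],
    [90.9, 89.1, 84.0, 67.4],
    [92.4, 88.9, 81.1, 59.0],
])
PUBLISHED_AUC_PCT = 96.1


def objective(bot_mean: float, bot_sd: float) -> float:
    model = TwoNormalNRI(human_mean=0.0, human_sd=1.0,
                         bot_mean=bot_mean, bot_sd=bot_sd)
    table = theory_accuracy_table(model, TABLE1_CONTAMINATION_ROWS,
                                  TABLE1_SPECIFICITY_COLS)
    err_table = np.abs(table - PUBLISHED_TABLE).max()
    err_auc = abs(round(100.0 * two_normal_auc(model), 1) - PUBLISHED_AUC_PCT)
    return max(err_table, err_auc)


def solve(mean_grid=None, sd_grid=None) -> tuple[float, float, float]:
    """Vectorized grid search; returns (bot mean, bot sd, max deviation)."""
    from scipy import stats

    if mean_grid is None:
        mean_grid = np.round(np.arange(0.5, 4.0001, 0.01), 2)
    if sd_grid is None:
        sd_grid = np.round(np.arange(0.5, 2.0001, 0.01), 2)
    spec = np.asarray(TABLE1_SPECIFICITY_COLS)
    lam = np.asarray(TABLE1_CONTAMINATION_ROWS)
    cutoffs = stats.norm.ppf(spec)  # humans standardized to N(0, 1)
    mu = mean_grid[:, None, None, None]
    sd = sd_grid[None, :, None, None]
    sens = 1.0 - stats.norm.cdf((cutoffs[None, None, None, :] - mu) / sd)
    acc = lam[None, None, :, None] * sens + (1 - lam[None, None, :, None]) * spec
    table = np.round(100.0 * acc, 1)
    err_table = np.abs(table - PUBLISHED_TABLE[None, None]).max(axis=(2, 3))
    auc = np.round(100.0 * stats.norm.cdf(
        mean_grid[:, None] / np.hypot(1.0, sd_grid[None, :])), 1)
    err = np.maximum(err_table, np.abs(auc - PUBLISHED_AUC_PCT))
    i, j = np.unravel_index(np.argmin(err), err.shape)
    return float(mean_grid[i]), float(sd_grid[j]), float(err[i, j])


if __name__ == "__main__":
    mu, sd, err = solve()
    print(f"bot mean = {mu}, bot sd = {sd}, max abs deviation = {err} pp")
    model = TwoNormalNRI(bot_mean=mu, bot_sd=sd)
    print(f"AUC = {100 * two_normal_auc(model):.1f}%")
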