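"""Exploratory summaries and scanpath visualization."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

SIGNIFICANCE = 0.05


def exploratory_summary(table: pd.DataFrame, sex_col: str = "sex") -> dict:
    """Pearson correlation matrix with p-values plus sex t-tests.

    ``table`` holds one row per subject with numeric columns (game, BVSCO,
    questionnaire, eye-tracking summaries) and optionally a sex column; each
    BVSCO exercise column (``c1``..``c3``) and the over-threshold count are
    compared between sexes with a two-sample t-test.  Constant columns have
    undefined correlations and are flagged.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects for exploratory summaries")
    numeric = table.select_dtypes(include=[np.number])
    cols = list(numeric.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    constant = [c for c in cols if numeric[c].nunique() <= 1]
    for i, a in enumerate(cols):
        for j in range(i + 1, k):
            b = cols[j]
            if a in constant or b in constant:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(numeric[a], numeric[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue

    ttests = {}
    if sex_col in table.columns and table[sex_col].nunique() == 2:
        levels = sorted(table[sex_col].unique())
        g1 = table[table[sex_col] == levels[0]]
        g2 = table[table[sex_col] == levels[1]]
        candidates = [c for c in ("c1", "c2", "c3", "n_over_threshold") if c in numeric.columns]
        for c in candidates:
            t, pv = stats.ttest_ind(g1[c], g2[c])
            ttests[c] = {
                "groups": levels,
                "means": [float(g1[c].mean()), float(g2[c].mean())],
                "t": float(t),
                "p": float(pv),
                "significant": bool(pv < SIGNIFICANCE),
            }
    return {
        "correlation_r": r,
        "correlation_p": p,
        "significant_pairs": [
            (a, b)
            for ai, a in enumerate(cols)
            for b in cols[ai + 1 :]
            if pd.notna(p.loc[a, b]) and p.loc[a, b] < SIGNIFICANCE
        ],
        "constant_columns": constant,
        "sex_ttests": ttests,
    }


def scanpath_plot(events: pd.DataFrame, partition=None, path=None, title: str | None = None):
    """Scatter a gaze or fixation stream colored by temporal rank.

    Darker markers are earlier events, brighter markers later ones; with a
    screen partition supplied, markers are additionally outlined by their
    assigned cluster.  Returns the matplotlib figure (saved to ``path`` when
    given); the output is deterministic for fixed input.
    """
    if len(events) == 0:
        raise ValueError("need at least one event to plot")
    tcol = "t" if "t" in events.columns else "t_start"
    order = events[tcol].rank(method="first").to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if partition is not None:
        clusters = partition.assign(events["x"], events["y"])
        cmap = plt.get_cmap("tab10")
        edge = [cmap(int(c) % 10) for c in clusters]
    else:
        edge = None
    ax.plot(events["x"], events["y"], color="0.85", lw=0.6, zorder=1)
    ax.scatter(
        events["x"],
        events["y"],
        c=order,
        cmap="viridis",
        s=22,
        edgecolors=edge,
        linewidths=0.8 if edge is not None else 0.0,
        zorder=2,
    )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("x (normalized)")
    ax.set_ylabel("y (normalized)")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=110, metadata={"Software": "scrivo"})
        plt.close(fig)
    return fig


def shap_beeswarm_plot(summary, path=None, max_features: int = 12):
    """Beeswarm-style strip plot of signed Shapley values, one row per
    feature ordered by mean |Shapley value|, colored by feature rank value."""
    feats = list(summary.mean_abs.index[:max_features])
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(feats) + 1.5))
    rng = np.random.default_rng(0)  # fixed jitter for deterministic output
    for row, f in enumerate(reversed(feats)):
        i = summary.feature_names.index(f)
        v = summary.values[:, i]
        jitter = rng.uniform(-0.18, 0.18, len(v))
        ax.scatter(v, np.full(len(v), row) + jitter, s=12, c=v, cmap="coolwarm", alpha=0.8)
    ax.axvline(0.0, color="0.4", lw=0.8)
    ax.set_yticks(range(len(feats)))
    ax.set_yticklabels(list(reversed(feats)), fontsize=7)
    ax.set_xlabel("Shapley value (log-odds)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110, metadata={"Software": "scrivo"})
        plt.close(fig)
    return fig
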