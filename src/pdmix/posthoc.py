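"""Tukey-Kramer pairwise comparison with compact letter display, paired t.

Conditions (distinct factor settings) are compared with the studentized-range
test on the pooled within-condition variance; unequal replicate counts use
the Kramer correction.  Conditions sharing a letter are not significantly
different at the chosen level.  Letters are assigned with the standard
insert-and-absorb algorithm, scanning conditions by descending mean, so the
display is independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TukeyGrouping", "tukey_letters", "PairedTResult", "paired_t"]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class TukeyGrouping:
    """Per-condition means with grouping letters and the pairwise p matrix."""

    table: pd.DataFrame  # condition, n, mean, letters (desc. mean order)
    pairwise_p: pd.DataFrame
    alpha: float
    df_error: int
    ms_error: float

    @property
    def n_classes(self) -> int:
        """Number of distinct letters used."""
        return len(set("".join(self.table["letters"])))

    def isolated(self) -> list[str]:
        """Conditions that share no letter with any other condition."""
        out = []
        for _, row in self.table.iterrows():
            mine = set(row["letters"])
            others = set(
                "".join(self.table.loc[self.table.condition != row["condition"],
                                       "letters"])
            )
            if not mine & others:
                out.append(row["condition"])
        return out

    def to_text(self) -> str:
        lines = [f"Tukey-Kramer grouping at {100 * (1 - self.alpha):g}% confidence"]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['condition']:>22s}  n={r['n']:<2d} mean={r['mean']:.2f}"
                f"  {r['letters']}"
            )
        return "\n".join(lines)


def _letter_columns(order: Sequence[int], differ: np.ndarray) -> list[set[int]]:
    """Insert-and-absorb compact letter display.

    ``order``: condition indices by descending mean.  ``differ[i, j]`` is
    True when i and j are significantly different.  Returns letter columns
    as sets of condition indices.
    """
    def absorb(columns: list[set[int]]) -> list[set[int]]:
        out: list[set[int]] = []
        for c in columns:
            if any(c < d for d in columns):  # proper subset of another column
                continue
            if c not in out:
                out.append(c)
        return out

    cols: list[set[int]] = [set(order)]
    for ai, a in enumerate(order):
        for b in order[ai + 1 :]:
            if not differ[a, b]:
                continue
            nxt: list[set[int]] = []
            for col in cols:
                if a in col and b in col:
                    nxt.append(col - {a})
                    nxt.append(col - {b})
                else:
                    nxt.append(col)
            cols = absorb(nxt)
    rank = {c: i for i, c in enumerate(order)}
    cols.sort(key=lambda c: min(rank[i] for i in c))
    return cols


def tukey_letters(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> TukeyGrouping:
    """Tukey-Kramer all-pairs comparison with letter grouping.

    Requires >= 2 conditions with >= 2 observations each.  With zero pooled
    variance the comparison degenerates to exact equality of means.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)})
    agg = df.groupby("group", sort=False)["value"].agg(["count", "mean", "var"])
    if len(agg) < 2:
        raise ValueError("need at least two conditions")
    if (agg["count"] < 2).any():
        raise ValueError("every condition needs at least two observations")
    g = len(agg)
    n_tot = int(agg["count"].sum())
    df_err = n_tot - g
    mse = float(((agg["count"] - 1) * agg["var"]).sum() / df_err)

    labels = [str(c) for c in agg.index]
    means = agg["mean"].to_numpy()
    ns = agg["count"].to_numpy()
    pmat = np.ones((g, g))
    differ = np.zeros((g, g), dtype=bool)
    for i in range(g):
        for j in range(i + 1, g):
            if mse > 0:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, g, df_err))
            else:
                p = 1.0 if means[i] == means[j] else 0.0
            pmat[i, j] = pmat[j, i] = p
            differ[i, j] = differ[j, i] = p < alpha

    order = list(np.argsort(-means, kind="stable"))
    cols = _letter_columns(order, differ)
    letters = {i: "" for i in range(g)}
    for li, col in enumerate(cols):
        for i in order:
            if i in col:
                letters[i] += _LETTERS[li]
    table = pd.DataFrame(
        {
            "condition": [labels[i] for i in order],
            "n": [int(ns[i]) for i in order],
            "mean": [means[i] for i in order],
            "letters": [letters[i] for i in order],
        }
    )
    pairwise = pd.DataFrame(pmat, index=labels, columns=labels)
    return TukeyGrouping(table=table, pairwise_p=pairwise, alpha=alpha,
                         df_error=df_err, ms_error=mse)


class PairedTResult(NamedTuple):
    t: float
    p: float
    mean_diff: float


def paired_t(before: Sequence[float], after: Sequence[float]) -> PairedTResult:
    """Two-sided paired t test on ``after - before``.

    Identical samples give (t=0, p=1).  Zero-variance nonzero differences
    have a degenerate t; the p-value is reported at its exact limit 0 with
    a warning.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    if np.all(d == 0):
        return PairedTResult(0.0, 1.0, 0.0)
    if np.std(d, ddof=1) == 0:
        warnings.warn("zero-variance nonzero differences; p is an exact limit")
        return PairedTResult(float(np.inf * np.sign(d.mean())), 0.0,
                             float(d.mean()))
    res = stats.ttest_rel(y, x)
    return PairedTResult(float(res.statistic), float(res.pvalue),
                         float(d.mean()))
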