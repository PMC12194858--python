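"""Repeatability statistics over repeated shots of the same wounds.

The design: N wounds are each photographed m times (at varying camera
heights); the calibrated ratio (or cm^2 area) forms an N x m grid.
Agreement across shots is then assessed with per-shot means +/- SD,
pairwise Pearson correlations, pairwise paired t-tests, and a one-way
ANOVA across the m shot groups.  All p-values are two-sided; standard
deviations use the n-1 denominator.

The ANOVA is deliberately the plain one-way between-shots test on the
same wounds (not a repeated-measures model): extremely high
between-wound variance relative to between-shot variance then shows up
as an F-statistic near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateStatisticsError, InvalidInputError

__all__ = [
    "RepeatabilityReport",
    "column_summary",
    "pearson",
    "paired_t",
    "one_way_anova",
    "repeatability_report",
]


def _as_grid(data) -> np.ndarray:
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise InvalidInputError("need an N x m grid with N >= 2 wounds, m >= 2 shots")
    if not np.isfinite(a).all():
        raise InvalidInputError("grid contains missing or non-finite cells")
    return a


def column_summary(data) -> tuple[np.ndarray, np.ndarray]:
    """Per-shot sample mean and sample SD (n-1 denominator)."""
    a = _as_grid(data)
    return a.mean(axis=0), a.std(axis=0, ddof=1)


def pearson(x, y) -> float:
    """Product-moment correlation of two shot columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("x and y must be equal-length vectors, n >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticsError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def paired_t(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns (t, p, df).

    t = mean(d) / (sd(d)/sqrt(N)) with d = x - y, df = N - 1.  Exactly
    identical columns give zero-variance differences, for which the
    statistic is undefined (the |t| -> infinity limit of a vanishing
    but constant offset); that configuration is rejected explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidInputError("x and y must be equal-length vectors, n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateStatisticsError(
            "differences have zero variance; the paired t statistic is undefined"
        )
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), x.size - 1


def one_way_anova(columns) -> tuple[float, float]:
    """One-way ANOVA across the m shot groups; returns (F, p).

    Degrees of freedom (m-1, m(N-1)); p from the F distribution's
    upper tail.
    """
    cols = [np.asarray(c, dtype=float) for c in columns]
    if len(cols) < 2 or any(c.size < 2 for c in cols):
        raise InvalidInputError("need >= 2 groups of >= 2 values")
    if np.std(np.concatenate(cols)) == 0:
        return 0.0, 1.0
    res = sps.f_oneway(*cols)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return f, p


@dataclass
class RepeatabilityReport:
    """Assembled agreement statistics for an N x m measurement grid."""

    labels: list[str]
    means: np.ndarray
    sds: np.ndarray
    pearson_r: dict[tuple[int, int], float]
    paired_tests: dict[tuple[int, int], tuple[float, float, int]]
    anova_f: float
    anova_p: float
    alpha: float

    @property
    def significant_pairs(self) -> list[tuple[int, int]]:
        """Shot pairs whose paired-t p-value falls below alpha."""
        return [pair for pair, (_, p, _) in self.paired_tests.items() if p < self.alpha]

    @property
    def consistent(self) -> bool:
        """True when no pairwise or omnibus test is significant."""
        return not self.significant_pairs and self.anova_p >= self.alpha

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.labels):
            rows.append({"shot": lab, "mean": self.means[j], "sd": self.sds[j]})
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), (t, p, df) in self.paired_tests.items():
            rows.append(
                {
                    "pair": f"{self.labels[i]} vs {self.labels[j]}",
                    "pearson_r": self.pearson_r[(i, j)],
                    "t": t,
                    "p": p,
                    "df": df,
                    "significant": p < self.alpha,
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Per-shot summary (mean +/- SD):"]
        for j, lab in enumerate(self.labels):
            lines.append(f"  {lab}: {self.means[j]:.2f} +/- {self.sds[j]:.2f}")
        lines.append("Pairwise agreement:")
        for (i, j), (t, p, df) in self.paired_tests.items():
            lines.append(
                f"  {self.labels[i]} vs {self.labels[j]}: "
                f"r={self.pearson_r[(i, j)]:.3f}, t={t:.3f} (df={df}), p={p:.3f}"
                f"{'  *' if p < self.alpha else ''}"
            )
        lines.append(f"ANOVA: F={self.anova_f:.4f}, p={self.anova_p:.4f}")
        lines.append(
            "Verdict: "
            + (
                "no significant differences across shots"
                if self.consistent
                else "significant shot differences detected"
            )
        )
        return "\n".join(lines)


def repeatability_report(data, alpha: float = 0.05, labels=None) -> RepeatabilityReport:
    """Full statistical battery over an N wounds x m shots grid."""
    a = _as_grid(data)
    n, m = a.shape
    labels = list(labels) if labels is not None else [f"shot{j + 1}" for j in range(m)]
    if len(labels) != m:
        raise InvalidInputError("label count must match the number of shots")
    means, sds = column_summary(a)
    pearson_r = {}
    paired = {}
    for i, j in combinations(range(m), 2):
        pearson_r[(i, j)] = pearson(a[:, i], a[:, j])
        paired[(i, j)] = paired_t(a[:, i], a[:, j])
    f, p = one_way_anova([a[:, j] for j in range(m)])
    return RepeatabilityReport(
        labels=labels,
        means=means,
        sds=sds,
        pearson_r=pearson_r,
        paired_tests=paired,
        anova_f=f,
        anova_p=p,
        alpha=alpha,
    )
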