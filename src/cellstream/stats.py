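"""Group comparison statistics.

The unit of replication throughout is the independent recording (a time-lapse
field) or physical section — never the individual cell or PIV node.  Groups of
per-recording scalars are summarised as mean ± SEM and compared with
two-tailed Welch t-tests, which assume neither equal variance nor pairing.
No multiple-testing correction is applied; reports list raw p-values together
with the number of comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = ["SampleSet", "WelchResult", "welch_t", "sem", "group_report"]


@dataclass
class SampleSet:
    """Named group of per-recording scalar values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(a: SampleSet, b: SampleSet) -> WelchResult:
    """Two-tailed Welch t-test with Welch–Satterthwaite degrees of freedom.

    Degenerate cases: two identical constant groups compare equal (t = 0,
    p = 1 by convention); zero pooled variance with unequal means has no
    finite t and is flagged degenerate (p = 0, infinite t).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 independent samples")
    va = np.var(a.values, ddof=1)
    vb = np.var(b.values, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a.values) == np.mean(b.values):
            return WelchResult(t=0.0, df=float(a.n + b.n - 2), p=1.0, degenerate=True)
        sign = math.copysign(1.0, float(np.mean(a.values) - np.mean(b.values)))
        return WelchResult(
            t=sign * math.inf, df=float(a.n + b.n - 2), p=0.0, degenerate=True
        )
    res = scipy.stats.ttest_ind(a.values, b.values, equal_var=False)
    sa, sb = va / a.n, vb / b.n
    df = (sa + sb) ** 2 / (sa**2 / (a.n - 1) + sb**2 / (b.n - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def sem(values) -> float:
    """Standard error of the mean: sample sd (n−1 denominator) / √n."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


@dataclass
class GroupReport:
    """Two-group comparison across one or more metrics."""

    group_a: str
    group_b: str
    metrics: dict = field(default_factory=dict)
    n_comparisons: int = 0

    def to_dict(self) -> dict:
        return {
            "groups": [self.group_a, self.group_b],
            "n_comparisons": self.n_comparisons,
            "metrics": self.metrics,
        }

    def to_text(self) -> str:
        lines = [
            f"Comparison: {self.group_a} vs {self.group_b} "
            f"({self.n_comparisons} metrics, Welch t-test, raw p)"
        ]
        for name, entry in self.metrics.items():
            ga = entry[self.group_a]
            gb = entry[self.group_b]
            lines.append(
                f"  {name}: {ga['mean']:.4g} ± {ga['sem']:.3g} (n={ga['n']}) vs "
                f"{gb['mean']:.4g} ± {gb['sem']:.3g} (n={gb['n']}), "
                f"t={entry['welch']['t']:.3g}, df={entry['welch']['df']:.3g}, "
                f"p={entry['welch']['p']:.3g}"
            )
        return "\n".join(lines)


def group_report(groups: dict[str, dict[str, list]]) -> GroupReport:
    """Compare two groups of per-recording results metric by metric.

    ``groups`` maps exactly two group labels to ``{metric: [values]}`` dicts;
    the metric names must coincide between groups.
    """
    if len(groups) != 2:
        raise ValueError("group_report compares exactly two groups")
    (la, da), (lb, db) = groups.items()
    if not da or not db:
        raise ValueError("empty group")
    if set(da) != set(db):
        raise ValueError(
            f"metric names differ between groups: {sorted(da)} vs {sorted(db)}"
        )
    report = GroupReport(group_a=la, group_b=lb, n_comparisons=len(da))
    for metric in da:
        a = SampleSet(la, da[metric])
        b = SampleSet(lb, db[metric])
        res = welch_t(a, b)
        report.metrics[metric] = {
            la: {"mean": float(np.mean(a.values)), "sem": sem(a.values), "n": a.n},
            lb: {"mean": float(np.mean(b.values)), "sem": sem(b.values), "n": b.n},
            "welch": {
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "degenerate": res.degenerate,
            },
        }
    return report
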