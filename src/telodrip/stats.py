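"""Statistical comparison procedure and report rendering.

The comparison of two groups follows an assumption-gated decision tree:
normality of each group (Shapiro-Wilk; of the paired differences as well
when samples are paired) and homoscedasticity across groups (Levene's test,
median-centred, i.e. Brown-Forsythe) are tested at the same alpha as the
main comparison.  When every gate passes, a two-tailed Student's t-test
(paired or unpaired) is used; otherwise the matching non-parametric test —
Wilcoxon signed-rank for paired samples, Wilcoxon rank-sum (Mann-Whitney U)
for unpaired.  The branch actually taken and the gate p-values that chose
it are recorded in the result.

Signed-rank p-values are exact (full enumeration) for small samples without
ties, normal approximation with continuity/tie correction otherwise.  The
two-sample proportions test is the chi-square test of equal proportions
with Yates continuity correction, two-sided.  All tests are two-sided and
no multiple-testing correction is applied by default (raw p-values are
reported); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    paired: bool
    branch_taken: str                 # "parametric" | "nonparametric"
    alpha: float
    gates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _shapiro_p(x: np.ndarray) -> float:
    # constant input has no defined normality; treat as a failed gate
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def select_and_compare(a, b, paired: bool, alpha: float = 0.05,
                       levene_center: str = "median") -> TestResult:
    """Compare two sample vectors via the gated parametric/non-parametric
    decision tree described above."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal lengths")

    gates = {"shapiro_a": _shapiro_p(a), "shapiro_b": _shapiro_p(b)}
    if paired:
        gates["shapiro_diff"] = _shapiro_p(a - b)
    gates["levene"] = float(sps.levene(a, b, center=levene_center).pvalue)

    constant = np.ptp(a) == 0 or np.ptp(b) == 0 or \
        (paired and np.ptp(a - b) == 0)
    if constant:
        warnings.warn("constant input vector; forcing non-parametric branch",
                      stacklevel=2)
    parametric = (not constant) and all(p >= alpha for p in gates.values())

    if parametric:
        if paired:
            stat, p = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            stat, p = sps.ttest_ind(a, b)
            name = "t-test"
    elif paired:
        name = "wilcoxon signed-rank"
        diffs = a - b
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0  # no non-zero differences to rank
        else:
            stat, p = sps.wilcoxon(a, b, zero_method="wilcox",
                                   correction=True, method="auto")
    else:
        name = "mann-whitney u"
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="auto")
    return TestResult(
        test_name=name, statistic=float(stat), p_value=float(p),
        n=(len(a), len(b)), paired=paired,
        branch_taken="parametric" if parametric else "nonparametric",
        alpha=alpha, gates=gates)


def proportions_test(k1: int, n1: int, k2: int, n2: int,
                     alpha: float = 0.05) -> TestResult:
    """Two-sample test of equal proportions (chi-square, Yates-corrected,
    two-sided) on k1/n1 vs k2/n2 successes."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k1 * n2 == k2 * n1:  # identical proportions; chi-square degenerates
        stat, p = 0.0, 1.0
    else:
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        res = sps.chi2_contingency(table, correction=True)
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        test_name="proportions chi-square", statistic=stat, p_value=p,
        n=(n1, n2), paired=False, branch_taken="parametric", alpha=alpha)


def repeated_measures_anova(matrix, alpha: float = 0.05) -> TestResult:
    """One-way repeated-measures ANOVA across loci (columns), subjects as
    rows.  Classic within-subject sum-of-squares decomposition; missing
    cells are an error (no imputation)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete samples x loci matrix, >= 2 each")
    if np.any(np.isnan(X)):
        raise ValueError("missing cells in repeated-measures matrix")
    n, k = X.shape
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_subj = float(k * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_treat = float(n * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_treat
    df_treat = k - 1
    df_err = (n - 1) * (k - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_treat == 0 else float("inf")
        p = 1.0 if ms_treat == 0 else 0.0
    else:
        f = ms_treat / ms_err
        p = float(sps.f.sf(f, df_treat, df_err))
    return TestResult(
        test_name="repeated-measures ANOVA", statistic=float(f), p_value=p,
        n=(n, k), paired=True, branch_taken="parametric", alpha=alpha)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        prev = min(prev, p[idx] * m / i)
        adj[idx] = prev
    return adj


def results_table(results: Mapping[str, TestResult]) -> pd.DataFrame:
    rows = []
    for label, r in results.items():
        rows.append({
            "comparison": label, "test": r.test_name,
            "statistic": r.statistic, "p_value": r.p_value,
            "branch": r.branch_taken, "n": "x".join(map(str, r.n)),
            "alpha": r.alpha,
            **{f"gate_{k}": v for k, v in r.gates.items()},
        })
    return pd.DataFrame(rows)


def render_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: Optional[Mapping] = None,
                  log_lines: Sequence[str] = ()) -> list[Path]:
    """Write every summary table as ``<name>.csv`` plus a run log echoing
    the configuration.  Raises when the cohort produced no rows at all."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if tables and all(df.empty for df in tables.values()):
        raise ValueError("empty cohort: no rows in any summary table")
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    log = out_dir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write("# run log\n")
        if config is not None:
            import yaml

            fh.write("# configuration\n")
            fh.write(yaml.safe_dump(dict(config), sort_keys=True))
        for line in log_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(f"tables written: {', '.join(p.name for p in written)}\n")
    written.append(log)
    return written
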