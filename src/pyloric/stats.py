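"""Normality-gated inference and report assembly.

The study's statistical recipe: test paired differences for normality
(Shapiro-Wilk), use a paired Student's t-test when normal and a Wilcoxon
signed-rank test otherwise; one-way repeated-measures ANOVA with post-hoc
Tukey HSD for three-condition within-subject designs; Bonferroni
adjustment across families of slope tests; Pearson correlation for
association.  ``build_report`` bundles module summaries into a
deterministic JSON/Markdown report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSample",
    "TestResult",
    "normality_gate",
    "paired_compare",
    "one_sample_compare",
    "rm_anova_tukey",
    "bonferroni",
    "pearson_corr",
    "build_report",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements (a, b) across experiments, aligned by label."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise StatsError("paired sample arrays must be 1-D and equal length")
        if len(self.labels) != a.size:
            raise StatsError("labels must match sample length")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise StatsError("paired sample values must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class TestResult:
    """One inferential result with its provenance."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    normality_p: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "p_adjusted": self.p_adjusted,
            "normality_p": self.normality_p,
        }
        d.update(self.extra)
        return d


def normality_gate(differences) -> tuple[str, float]:
    """Shapiro-Wilk normality gate on paired differences.

    Returns ``("normal", p)`` when the Shapiro-Wilk p-value exceeds 0.05,
    else ``("non_normal", p)``.  Zero-variance differences are degenerate
    and routed to the non-normal branch with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise StatsError("normality gate needs n >= 3")
    if np.ptp(d) == 0:
        warnings.warn("constant differences: normality undefined, treating as non-normal",
                      stacklevel=2)
        return "non_normal", float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(d)
    return ("normal" if p > SHAPIRO_ALPHA else "non_normal"), float(p)


def paired_compare(sample: PairedSample) -> TestResult:
    """Two-sided paired comparison routed through the normality gate.

    Normal differences use a paired Student's t-test; non-normal use the
    Wilcoxon signed-rank test (zero differences split between signs, so an
    identical pair yields statistic 0 and p = 1 rather than an error).
    """
    d = sample.differences
    if np.all(d == 0):
        # identical pairs: no evidence against the null by construction
        return TestResult(
            test_name="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n=int(d.size),
            normality_p=float("nan"),
        )
    gate, normality_p = normality_gate(d)
    if gate == "normal":
        stat, p = sps.ttest_rel(sample.a, sample.b)
        name = "paired_t"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.wilcoxon(d, zero_method="zsplit")
        name = "wilcoxon_signed_rank"
    return TestResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n=int(d.size),
        normality_p=normality_p,
    )


def one_sample_compare(values, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample test against ``popmean``, normality-gated.

    Used for slope-vs-zero tests of phase constancy: one-sample t when the
    values are normal, Wilcoxon signed-rank on ``values - popmean``
    otherwise.
    """
    v = np.asarray(values, dtype=float)
    gate, normality_p = normality_gate(v - popmean)
    if gate == "normal":
        stat, p = sps.ttest_1samp(v, popmean)
        name = "one_sample_t"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.wilcoxon(v - popmean, zero_method="zsplit")
        name = "wilcoxon_signed_rank"
    return TestResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n=int(v.size),
        normality_p=normality_p,
    )


def rm_anova_tukey(data: pd.DataFrame, alpha: float = 0.05) -> list[TestResult]:
    """One-way repeated-measures ANOVA with post-hoc Tukey HSD.

    ``data`` must be long-format with columns ``subject``, ``condition``
    and ``value``, complete (every subject measured in every condition; no
    imputation).  Tukey contrasts are computed only when the omnibus F is
    significant at ``alpha``; they are run on subject-centered values so
    the pairwise error term reflects within-subject variability, matching
    the repeated-measures omnibus (reported mean differences are unchanged
    by centering).
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    required = {"subject", "condition", "value"}
    if not required.issubset(data.columns):
        raise StatsError(f"data must have columns {sorted(required)}")
    counts = data.groupby(["subject", "condition"]).size()
    n_cond = data["condition"].nunique()
    per_subject = counts.groupby("subject").size()
    if (counts != 1).any() or (per_subject != n_cond).any():
        raise StatsError("repeated-measures design must be complete, one value per cell")
    if n_cond < 2:
        raise StatsError("need at least two conditions")

    res = AnovaRM(data, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    f_result = TestResult(
        test_name="rm_anova",
        statistic=float(row["F Value"]),
        p_value=float(row["Pr > F"]),
        n=int(data["subject"].nunique()),
        extra={"df_num": float(row["Num DF"]), "df_den": float(row["Den DF"])},
    )
    results = [f_result]
    if f_result.p_value < alpha and n_cond > 2:
        centered = data["value"] - data.groupby("subject")["value"].transform("mean")
        hsd = pairwise_tukeyhsd(
            centered.to_numpy(), data["condition"].to_numpy(), alpha=alpha
        )
        summary = hsd.summary()
        for line in summary.data[1:]:
            g1, g2, meandiff, p_adj, lower, upper, reject = line
            results.append(
                TestResult(
                    test_name="tukey_hsd",
                    statistic=float(meandiff),
                    p_value=float(p_adj),
                    p_adjusted=float(p_adj),
                    n=f_result.n,
                    extra={
                        "group_1": str(g1),
                        "group_2": str(g2),
                        "reject": bool(reject),
                    },
                )
            )
    return results


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the number of p-values and must be at least that
    (the study's phase-constancy family uses m = 10: 5 phases x 2
    conditions).
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise StatsError(f"m={m} is smaller than the number of tests ({p.size})")
    return np.minimum(1.0, m * p)


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("pearson_corr needs equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("pearson_corr is undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(test_name="pearson", statistic=float(r), p_value=float(p), n=int(x.size))


def _jsonable(obj):
    """Recursively convert summaries/dataclasses/arrays to JSON-safe values."""
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def build_report(sections: dict) -> dict:
    """Assemble module summaries into a deterministic report bundle.

    ``sections`` maps section names to summary objects (anything exposing
    ``to_dict``; plain dicts/lists/scalars pass through).  Empty or None
    sections are omitted.  Returns ``{"json": <str>, "markdown": <str>,
    "data": <dict>}``; rerunning on identical inputs is byte-identical.
    """
    if not sections:
        raise StatsError("build_report needs at least one summary")
    data = {k: _jsonable(v) for k, v in sorted(sections.items()) if v is not None}
    data = {k: v for k, v in data.items() if v not in ({}, [])}
    payload = json.dumps(data, indent=2, sort_keys=True)

    lines = ["# Pyloric analysis report", ""]
    for name, content in data.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.extend(_markdown_section(content))
        lines.append("")
    return {"json": payload, "markdown": "\n".join(lines), "data": data}


def _fmt(v) -> str:
    if v is None:
        return "–"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _markdown_section(content) -> list[str]:
    if isinstance(content, dict) and content and all(
        isinstance(v, dict) for v in content.values()
    ):
        # grid: rows = inner keys, columns = outer keys (Table-1-shaped)
        cols = list(content.keys())
        rows = sorted({rk for v in content.values() for rk in v})
        out = ["| | " + " | ".join(cols) + " |", "|---" * (len(cols) + 1) + "|"]
        for rk in rows:
            cells = [_fmt(content[c].get(rk)) for c in cols]
            out.append(f"| {rk} | " + " | ".join(cells) + " |")
        return out
    if isinstance(content, dict):
        return [f"- **{k}**: {_fmt(v)}" for k, v in content.items()]
    if isinstance(content, list):
        return [f"- {_fmt(v)}" for v in content]
    return [_fmt(content)]
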