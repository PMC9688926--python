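"""Statistical layer for the growth pipeline and companion assays.

Normality gating (Shapiro-Wilk) routes data to either a pooled two-sample
t-test (small normal samples, e.g. MTS viability replicates) or rank tests:
Mann-Whitney U for two groups (e.g. the two conditions' 97-point median NPA
series, treated as observations as in the original analysis; the temporal
autocorrelation caveat is recorded in the result metadata, not "corrected"),
and Kruskal-Wallis with Bonferroni-adjusted post-hoc pairwise comparisons
(Dunn's rank z-test by default) for three or more groups, e.g. per-field
Ki67 percent-positive counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_ALT = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    alternative: str = "two_sided"
    adjusted: bool = False
    details: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def shapiro_wilk_gate(values) -> tuple[StatResult, str]:
    """Shapiro-Wilk normality test plus a parametric/nonparametric routing.

    Recommends ``nonparametric`` when p < 0.05. Requires 3 <= n <= 5000 and
    non-constant data (W is undefined at zero variance).
    """
    x = np.asarray(values, dtype=np.float64)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk W undefined for constant data")
    w, p = sps.shapiro(x)
    res = StatResult("shapiro_wilk", float(w), float(p), (x.size,))
    return res, ("nonparametric" if p < 0.05 else "parametric")


def two_sample_t(
    a, b, alternative: str = "two_sided", equal_var: bool = True
) -> StatResult:
    """Two-sample t-test, pooled variance by default (Welch selectable).

    Zero pooled variance: equal means give the t = 0, p = 1 convention;
    unequal means are flagged degenerate (infinite t, p = 0).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    details: dict = {"equal_var": equal_var}
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float("inf") if a.mean() > b.mean() else float("-inf")
            p = 0.0
            details["degenerate"] = True
        return StatResult(
            "two_sample_t", t, p, (a.size, b.size), alternative, details=details
        )
    t, p = sps.ttest_ind(a, b, equal_var=equal_var, alternative=_ALT[alternative])
    return StatResult(
        "two_sample_t", float(t), float(p), (a.size, b.size), alternative,
        details=details,
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a, b, alternative: str = "two_sided", exact_threshold: int = 8
) -> StatResult:
    """Mann-Whitney U test (U statistic of the first sample).

    The p-value is exact (full null distribution of U) when both groups have
    at most ``exact_threshold`` observations and the pooled data are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    exact = (
        a.size <= exact_threshold
        and b.size <= exact_threshold
        and not _has_ties(a, b)
    )
    method = "exact" if exact else "asymptotic"
    u, p = sps.mannwhitneyu(
        a, b, alternative=_ALT[alternative], method=method, use_continuity=True
    )
    return StatResult(
        "mann_whitney_u",
        float(u),
        float(p),
        (a.size, b.size),
        alternative,
        details={
            "method": method,
            "caveat": "observations treated as independent; serial "
            "correlation of time-series inputs is not corrected",
        },
    )


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi^2 with k-1 df.

    All-identical data give H = 0, p = 1 (no evidence of any difference).
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2 or any(g.size < 1 for g in arrays):
        raise ValueError("need >= 2 groups with n >= 1 each")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need total N >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return StatResult(
            "kruskal_wallis", 0.0, 1.0, tuple(g.size for g in arrays),
            details={"degenerate": "all values identical"},
        )
    h, p = sps.kruskal(*arrays)
    return StatResult(
        "kruskal_wallis", float(h), float(p), tuple(g.size for g in arrays)
    )


def posthoc_bonferroni(
    groups,
    method: str = "dunn",
    names: list[str] | None = None,
    alternative: str = "two_sided",
) -> list[StatResult]:
    """All pairwise post-hoc comparisons with Bonferroni adjustment.

    ``dunn`` (default) compares mean ranks of the pooled ranking by a
    normal z-test with tie correction — the usual follow-up to a
    Kruskal-Wallis test in mainstream statistical suites; ``pairwise_mw``
    runs plain pairwise Mann-Whitney tests instead. Raw p-values are
    multiplied by the number of pairs and capped at 1.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    k = len(arrays)
    names = names or [f"group{i + 1}" for i in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    results = []
    if method == "dunn":
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        n_total = pooled.size
        bounds = np.cumsum([0] + [g.size for g in arrays])
        mean_ranks = [
            ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)
        ]
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_base = n_total * (n_total + 1) / 12.0
        if n_total > 1:
            var_base -= tie_term / (12.0 * (n_total - 1))
        for i, j in pairs:
            se2 = var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            if se2 <= 0:
                z, raw = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
                raw = float(2.0 * sps.norm.sf(abs(z)))
            results.append(
                StatResult(
                    "dunn",
                    float(z),
                    min(1.0, m * raw),
                    (arrays[i].size, arrays[j].size),
                    alternative,
                    adjusted=True,
                    details={
                        "pair": (names[i], names[j]),
                        "raw_p": raw,
                        "n_comparisons": m,
                    },
                )
            )
    elif method == "pairwise_mw":
        for i, j in pairs:
            r = mann_whitney_u(arrays[i], arrays[j], alternative)
            results.append(
                StatResult(
                    "pairwise_mann_whitney",
                    r.statistic,
                    min(1.0, m * r.p_value),
                    r.n_per_group,
                    alternative,
                    adjusted=True,
                    details={
                        "pair": (names[i], names[j]),
                        "raw_p": r.p_value,
                        "n_comparisons": m,
                    },
                )
            )
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return results


def mts_normalize(table: pd.DataFrame, control: str) -> pd.DataFrame:
    """Normalize assay values to the mean of the control condition.

    ``table`` needs ``condition`` and ``value`` columns; returns a copy with
    ``value`` divided by the control mean (so the control's normalized mean
    is exactly 1).
    """
    sub = table.loc[table["condition"] == control, "value"]
    if sub.empty:
        raise KeyError(f"control condition {control!r} not present")
    mean = float(sub.mean())
    if mean <= 0:
        raise ValueError("control mean must be positive")
    out = table.copy()
    out["value"] = out["value"] / mean
    return out


def ki67_percent(fields: pd.DataFrame) -> pd.DataFrame:
    """Percent positive cells per visual field.

    ``fields`` needs ``positive_count`` and ``total_count`` columns; adds a
    ``percent_positive`` column (100 * positive / total).
    """
    if (fields["total_count"] <= 0).any():
        raise ValueError("total_count must be positive in every field")
    if (fields["positive_count"] < 0).any() or (
        fields["positive_count"] > fields["total_count"]
    ).any():
        raise ValueError("positive_count must lie in [0, total_count]")
    out = fields.copy()
    out["percent_positive"] = 100.0 * out["positive_count"] / out["total_count"]
    return out


def results_to_dataframe(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        pair = r.details.get("pair")
        rows.append(
            {
                "test": r.test_name,
                "groups": " vs ".join(pair) if pair else "",
                "n": "x".join(str(n) for n in r.n_per_group),
                "statistic": r.statistic,
                "raw_p": r.details.get("raw_p", r.p_value if not r.adjusted else np.nan),
                "p_value": r.p_value,
                "adjusted": r.adjusted,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)
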