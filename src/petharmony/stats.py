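"""Ordinal concordance statistics for paired Deauville scores.

Cross-tabulation, discordance summaries, and the paired testing
procedure: a Friedman test over the three settings followed by pairwise
Wilcoxon signed-rank post-hoc tests at a Bonferroni-corrected level.

The signed-rank test uses the convention that reproduces SPSS-style
published values for heavily tied ordinal differences: zero differences
are dropped, absolute differences receive midranks, the normal
approximation uses the tie-corrected variance, and no continuity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "PairedScores",
    "TestResult",
    "crosstab",
    "pairs_from_crosstab",
    "discordance_count",
    "major_discordance_count",
    "wilcoxon_signed_rank",
    "friedman",
    "bonferroni",
    "compare_settings",
]


@dataclass
class ContingencyTable:
    """K x K cross-tabulation of ordinal scores from two settings."""

    counts: np.ndarray
    row_levels: tuple[int, ...]
    col_levels: tuple[int, ...]
    row_method: str = "method_a"
    col_method: str = "method_b"
    metric: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.row_levels = tuple(int(v) for v in self.row_levels)
        self.col_levels = tuple(int(v) for v in self.col_levels)
        if self.counts.shape != (len(self.row_levels), len(self.col_levels)):
            raise ValueError("counts shape does not match level labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index([f"DS{v}" for v in self.row_levels], name=self.row_method),
            columns=pd.Index([f"DS{v}" for v in self.col_levels], name=self.col_method),
        )


@dataclass
class PairedScores:
    """Multiset of (first, second) ordinal score pairs."""

    pairs: list[tuple[int, int]]
    row_method: str = "method_a"
    col_method: str = "method_b"

    def __post_init__(self):
        self.pairs = [(int(a), int(b)) for a, b in self.pairs]
        for a, b in self.pairs:
            if not (1 <= a <= 5 and 1 <= b <= 5):
                raise ValueError(f"scores must lie in 1..5, got ({a}, {b})")

    def differences(self) -> np.ndarray:
        """Second minus first, one entry per pair."""
        return np.array([b - a for a, b in self.pairs], dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TestResult:
    test_name: str
    statistic: float | None
    p_value: float | None
    z_value: float | None = None
    n_effective: int = 0
    df: int | None = None
    correction: str = "none"
    alpha_effective: float = 0.05
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value < self.alpha_effective


def crosstab(
    pairs: PairedScores, levels: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> ContingencyTable:
    """Cross-tabulate paired scores over the given ordered levels."""
    idx = {v: i for i, v in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=int)
    for a, b in pairs.pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"score pair ({a}, {b}) outside levels {levels}")
        counts[idx[a], idx[b]] += 1
    return ContingencyTable(
        counts, tuple(levels), tuple(levels), pairs.row_method, pairs.col_method
    )


def pairs_from_crosstab(table: ContingencyTable) -> PairedScores:
    """Expand a cross-tabulation back into its multiset of score pairs."""
    pairs = []
    for i, a in enumerate(table.row_levels):
        for j, b in enumerate(table.col_levels):
            pairs.extend([(a, b)] * int(table.counts[i, j]))
    return PairedScores(pairs, table.row_method, table.col_method)


def discordance_count(table: ContingencyTable) -> tuple[int, float]:
    """Number and fraction of paired scores that differ between settings."""
    if table.counts.shape[0] != table.counts.shape[1]:
        raise ValueError("discordance requires a square table")
    if table.row_levels != table.col_levels:
        raise ValueError("row and column levels must match")
    n = table.total
    count = int(n - np.trace(table.counts))
    if n == 0:
        raise ValueError("empty table has no defined discordance fraction")
    return count, count / n


def major_discordance_count(table: ContingencyTable, boundary: int = 3) -> int:
    """Pairs whose scores fall on opposite sides of the responder boundary."""
    rows = np.asarray(table.row_levels)[:, None]
    cols = np.asarray(table.col_levels)[None, :]
    crossing = (rows <= boundary) != (cols <= boundary)
    return int(table.counts[crossing].sum())


def wilcoxon_signed_rank(
    pairs: PairedScores, alpha: float = 0.05, correction: str = "none", m: int = 1
) -> TestResult:
    """Paired signed-rank test on score differences (second - first).

    Zeros dropped, midranks for tied |d|, W+ = sum of positive ranks,
    z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48),
    two-sided p from the normal tail, no continuity correction.
    """
    d = pairs.differences()
    d = d[d != 0.0]
    n = d.size
    alpha_eff = bonferroni(alpha, m) if correction == "bonferroni" else alpha
    if n == 0:
        return TestResult(
            "wilcoxon_signed_rank", None, None, None, 0,
            correction=correction, alpha_effective=alpha_eff,
            flags=["all_differences_zero"],
        )
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts)).sum()
    ) / 48.0
    if var <= 0:
        return TestResult(
            "wilcoxon_signed_rank", w_pos, None, None, n,
            correction=correction, alpha_effective=alpha_eff,
            flags=["zero_variance"],
        )
    z = (w_pos - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        "wilcoxon_signed_rank", w_pos, float(p), float(z), n,
        correction=correction, alpha_effective=alpha_eff,
    )


def friedman(scores: np.ndarray) -> TestResult:
    """Friedman test over an (n studies x k settings) score matrix.

    Uses the tie-corrected chi-square approximation with k - 1 degrees of
    freedom (within-study midranks). Requires at least two complete rows.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 3:
        raise ValueError("friedman expects an (n, k>=3) matrix")
    complete = ~np.isnan(scores).any(axis=1)
    scores = scores[complete]
    n, k = scores.shape
    if n < 2:
        raise ValueError("friedman requires at least 2 complete studies")
    if np.all(scores == scores[:, [0]]):
        # every study ties across all settings: no evidence of any effect
        return TestResult("friedman", 0.0, 1.0, None, n, df=k - 1,
                          flags=["all_rows_tied"])
    stat, p = sps.friedmanchisquare(*[scores[:, j] for j in range(k)])
    return TestResult("friedman", float(stat), float(p), None, n, df=k - 1)


def bonferroni(alpha: float = 0.05, m: int = 3) -> float:
    """Bonferroni-corrected significance level, rounded to 4 decimals."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 4)


def compare_settings(
    scores: pd.DataFrame,
    metric: str | None = None,
    boundary: int = 3,
    alpha: float = 0.05,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict:
    """Full concordance report across reconstruction settings.

    ``scores`` is a tidy table with columns study_id, profile, score (and
    optionally metric to filter on). Studies missing any setting's score
    are excluded listwise. Emits every pairwise cross-tabulation with
    discordance and major-discordance counts and a Wilcoxon signed-rank
    test at the Bonferroni-corrected level; with three or more settings a
    Friedman test over the complete score matrix is included.
    """
    df = scores.copy()
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    df = df.dropna(subset=["score"])
    wide = df.pivot_table(index="study_id", columns="profile", values="score",
                          aggfunc="first")
    profiles = sorted(wide.columns)
    if len(profiles) < 2:
        raise ValueError("compare_settings requires at least 2 scored settings")
    complete = wide.dropna()
    n_excluded = len(wide) - len(complete)
    pair_names = list(combinations(profiles, 2))
    m = len(pair_names)
    report: dict = {
        "metric": metric,
        "n_studies": int(len(complete)),
        "n_excluded_incomplete": int(n_excluded),
        "profiles": profiles,
        "alpha": alpha,
        "alpha_bonferroni": bonferroni(alpha, m),
        "pairwise": {},
    }
    for a, b in pair_names:
        ps = PairedScores(
            [(int(x), int(y)) for x, y in zip(complete[a], complete[b])],
            row_method=a, col_method=b,
        )
        table = crosstab(ps, levels)
        count, frac = discordance_count(table)
        test = wilcoxon_signed_rank(ps, alpha=alpha, correction="bonferroni", m=m)
        report["pairwise"][f"{a}_vs_{b}"] = {
            "table": table,
            "discordant": count,
            "discordant_pct": round(100.0 * frac, 1),
            "major_discordant": major_discordance_count(table, boundary),
            "wilcoxon": test,
        }
    if len(profiles) >= 3:
        report["friedman"] = friedman(complete[profiles].to_numpy())
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a compare_settings report."""
    lines = [
        f"Concordance report ({report.get('metric') or 'all metrics'}): "
        f"n = {report['n_studies']} complete studies "
        f"({report['n_excluded_incomplete']} excluded)",
        f"Pairwise Wilcoxon at Bonferroni-corrected alpha = "
        f"{report['alpha_bonferroni']}",
    ]
    fr = report.get("friedman")
    if fr is not None and fr.p_value is not None:
        lines.append(
            f"Friedman chi2({fr.df}) = {fr.statistic:.3f}, p = {fr.p_value:.4g}"
        )
    for name, res in report["pairwise"].items():
        w = res["wilcoxon"]
        p_txt = "n/a" if w.p_value is None else f"{w.p_value:.4g}"
        lines.append(
            f"  {name}: discordant {res['discordant']} "
            f"({res['discordant_pct']}%), major {res['major_discordant']}, "
            f"Wilcoxon p = {p_txt}"
        )
        lines.append(res["table"].to_dataframe().to_string())
    return "\n".join(lines)
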