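"""Cohort statistics: group summaries, rank tests and rank correlations.

Mirrors the study's analysis plan: per-group mean ± SD tables, a
Kruskal-Wallis test across the fibrosis groups for each variable with
Dunn's post hoc pairwise comparisons (Bonferroni-adjusted), a
within-group Kruskal-Wallis across the 5/15/25-min time points as the
ECV-stability check, and Spearman rank correlations of ECV against
histology and portal pressure.  Time points are treated as independent
samples in the stability test, matching the study design rather than a
repeated-measures refinement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupSummary",
    "VariableTest",
    "CohortSummary",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "summarize_cohort",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation of one variable pair."""

    variable_pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics: variable → (mean, SD)."""

    group_label: str
    n: int
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class VariableTest:
    """Between-group rank test for one variable."""

    variable: str
    kruskal_h: float
    kruskal_p: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSummary:
    """Full analysis bundle for one synthetic or real cohort."""

    groups: list[GroupSummary]
    between_group: dict[str, VariableTest]
    time_stability: dict[str, tuple[float, float]]  # group → (H, p) for ECV over time
    correlations: list[CorrelationResult]

    def to_markdown(self) -> str:
        """Human-readable report of the summary tables and tests."""
        lines = ["# Cohort summary", "", "## Group characteristics (mean ± SD)", ""]
        variables = sorted({v for g in self.groups for v in g.stats})
        header = "| variable | " + " | ".join(
            f"{g.group_label} (n={g.n})" for g in self.groups
        ) + " | Kruskal-Wallis p |"
        lines += [header, "|" + "---|" * (len(self.groups) + 2)]
        for var in variables:
            cells = []
            for g in self.groups:
                if var in g.stats:
                    m, s = g.stats[var]
                    cells.append(f"{m:.1f} ± {s:.1f}")
                else:
                    cells.append("—")
            test = self.between_group.get(var)
            p_txt = f"{test.kruskal_p:.3g}" if test else "—"
            lines.append(f"| {var} | " + " | ".join(cells) + f" | {p_txt} |")
        if self.time_stability:
            lines += ["", "## ECV stability over time (within-group Kruskal-Wallis)", ""]
            for group, (h, p) in self.time_stability.items():
                lines.append(f"- {group}: H = {h:.3g}, p = {p:.3g}")
        if self.correlations:
            lines += ["", "## Spearman rank correlations", ""]
            for c in self.correlations:
                lines.append(
                    f"- {c.variable_pair[0]} vs {c.variable_pair[1]}: "
                    f"rho = {c.rho:.3f}, p = {c.p_value:.3g} (n = {c.n})"
                )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def _validate_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("need a total of at least 5 observations")
    return groups


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    All-identical observations return (0, 1) instead of tripping on the
    zero tie-correction denominator.
    """
    groups = _validate_groups(groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups, labels=None) -> dict[tuple[str, str], float]:
    """Dunn's pairwise comparisons on the pooled mid-ranks.

    z statistics use the tie-corrected pooled-rank variance; two-sided
    normal p-values are Bonferroni-multiplied by the number of pairs and
    capped at 1.
    """
    groups = _validate_groups(groups)
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per group required")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    n_pairs = k * (k - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        if var_factor <= 0:  # all observations identical
            out[(labels[i], labels[j])] = 1.0
            continue
        se = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out[(labels[i], labels[j])] = min(1.0, p * n_pairs)
    return out


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration (n < 10 only)."""
    n = len(rank_x)
    cx = rank_x - rank_x.mean()
    cy = rank_y - rank_y.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    perms = np.array(list(itertools.permutations(cy)))
    rho_perm = (perms @ cx) / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p below n = 10.

    rho is the Pearson correlation of mid-ranks.  For n >= 10 the p-value
    uses the usual t approximation with n - 2 degrees of freedom; for
    smaller samples every rank permutation is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    rank_x = sps.rankdata(x)
    rank_y = sps.rankdata(y)
    if np.ptp(rank_x) == 0.0 or np.ptp(rank_y) == 0.0:
        raise ValueError("undefined correlation: a variable has zero rank variance")
    rho = float(np.corrcoef(rank_x, rank_y)[0, 1])
    if n < 10:
        p = _exact_spearman_p(rank_x, rank_y, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(variable_pair=("x", "y"), rho=rho, p_value=p, n=n)


# ---------------------------------------------------------------------------
# Cohort-level summary
# ---------------------------------------------------------------------------

_TIME_TO_COLUMN = {"post5": "ecv_5min_pct", "post15": "ecv_15min_pct", "post25": "ecv_25min_pct"}


def _ecv_wide(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot ECV records to one row per subject, percent units."""
    wide = records.pivot_table(index="subject_id", columns="time_label", values="ecv")
    wide = wide.rename(columns=_TIME_TO_COLUMN) * 100.0
    return wide.reset_index()


def summarize_cohort(
    records: pd.DataFrame,
    ground_truth: pd.DataFrame,
    group_order: tuple[str, ...] | None = None,
) -> CohortSummary:
    """Full statistical read-out of a cohort.

    ``records`` is an ECV-record table (see :mod:`hepecv.ecv`) and
    ``ground_truth`` a cohort table (see :mod:`hepecv.kinetics`).  Emits
    the group-characteristics table with between-group Kruskal-Wallis and
    Dunn tests per variable, the within-group ECV-over-time stability
    test, and pooled Spearman correlations of ECV at each time point
    against the histology score and portal pressure.  With a single group
    present, only the descriptive summaries are produced.
    """
    wide = _ecv_wide(records)
    table = ground_truth.merge(wide, on="subject_id", how="left")
    if group_order is None:
        group_order = tuple(dict.fromkeys(table["group"]))

    variables = [
        "native_t1_liver_ms",
        "ecv_5min_pct",
        "ecv_15min_pct",
        "ecv_25min_pct",
        "sirius_red_pct",
        "portal_pressure_mmhg",
    ]
    variables = [v for v in variables if v in table.columns]

    groups_out = []
    for label in group_order:
        sub = table[table["group"] == label]
        stats_map = {
            v: (float(sub[v].mean()), float(sub[v].std(ddof=1)) if len(sub) > 1 else 0.0)
            for v in variables
            if sub[v].notna().any()
        }
        groups_out.append(GroupSummary(group_label=label, n=len(sub), stats=stats_map))

    between: dict[str, VariableTest] = {}
    if len(group_order) >= 2:
        for v in variables:
            samples = [
                table.loc[(table["group"] == g) & table[v].notna(), v].to_numpy()
                for g in group_order
            ]
            try:
                h, p = kruskal_wallis(samples)
                pairwise = dunn_posthoc(samples, labels=list(group_order))
            except ValueError:  # group empty or too few observations
                continue
            between[v] = VariableTest(variable=v, kruskal_h=h, kruskal_p=p, pairwise=pairwise)

    ecv_cols = [c for c in ("ecv_5min_pct", "ecv_15min_pct", "ecv_25min_pct") if c in table]
    stability: dict[str, tuple[float, float]] = {}
    if len(ecv_cols) >= 2:
        for label in group_order:
            sub = table[table["group"] == label]
            samples = [sub[c].dropna().to_numpy() for c in ecv_cols]
            try:
                stability[label] = kruskal_wallis(samples)
            except ValueError:
                continue

    correlations: list[CorrelationResult] = []
    for ecv_col in ecv_cols:
        for target in ("sirius_red_pct", "portal_pressure_mmhg"):
            if target not in table:
                continue
            sub = table[[ecv_col, target]].dropna()
            if len(sub) < 4:
                continue
            res = spearman(sub[ecv_col], sub[target])
            correlations.append(
                CorrelationResult(
                    variable_pair=(ecv_col, target),
                    rho=res.rho,
                    p_value=res.p_value,
                    n=res.n,
                )
            )
    return CohortSummary(
        groups=groups_out,
        between_group=between,
        time_stability=stability,
        correlations=correlations,
    )


def summary_table(summary: CohortSummary) -> pd.DataFrame:
    """Group-characteristics table as a tidy frame (one row per variable/group)."""
    rows = []
    for g in summary.groups:
        for var, (mean, sd) in g.stats.items():
            test = summary.between_group.get(var)
            rows.append(
                {
                    "variable": var,
                    "group": g.group_label,
                    "n": g.n,
                    "mean": mean,
                    "sd": sd,
                    "kruskal_h": test.kruskal_h if test else np.nan,
                    "kruskal_p": test.kruskal_p if test else np.nan,
                }
            )
    return pd.DataFrame(rows)
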