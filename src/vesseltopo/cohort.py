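"""Cohort analysis: baseline normalization, shell profiles, group statistics.

Longitudinal descriptor values are normalized per subject to day 0 (the day
treatment is administered, or observation starts). The spatiotemporal loop
profile divides the radial filtration into spherical shells around the tumor
center and tracks the median number of loops per vessel segment in each
shell over time, normalized by day 0 per shell.

Group comparisons follow the conventional nonparametric battery: a
Kruskal-Wallis test across all groups, then pairwise two-sided Wilcoxon
rank-sum tests against the control group, at significance level 0.05 and
without multiple-testing correction; exact small-sample p-values are used
where feasible. Descriptor relationships are summarized by pairwise Pearson
correlations with complete-linkage hierarchical clustering under the
Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .descriptors import compute_all
from .filtrations import radial_filtration
from .network import VesselNetwork
from .persistence import Barcode, persist_graph


# ---------------------------------------------------------------------------
# baseline normalization


def normalize_by_baseline(df: pd.DataFrame, value_cols: Sequence[str],
                          subject_col: str = "subject",
                          day_col: str = "day",
                          baseline_day=0) -> pd.DataFrame:
    """Divide each subject's values by its day-0 value.

    Zero or missing baselines give ``NaN`` in the normalized column and
    ``False`` in the companion ``<col>_baseline_defined`` column — cells are
    flagged as undefined, never silently dropped or turned into infinity.
    """
    out = df.copy()
    for col in value_cols:
        base = (df[df[day_col] == baseline_day]
                .set_index(subject_col)[col])
        base = base[~base.index.duplicated()]
        mapped = out[subject_col].map(base)
        defined = mapped.notna() & (mapped != 0)
        out[col + "_norm"] = np.where(defined, out[col] / mapped, np.nan)
        out[col + "_baseline_defined"] = defined.to_numpy()
    return out


# ---------------------------------------------------------------------------
# spatiotemporal shell profiles


@dataclass
class ShellProfile:
    """Loops per segment in radial shells per day, baseline-normalized.

    ``shells`` are bin edges; in relative mode they are fractions of each
    filtration's maximal radius, otherwise absolute micrometers. ``median``
    holds the across-tumor median per (day, shell); ``normalized`` the same
    divided by the day-0 row; ``undefined`` flags cells whose baseline is
    zero or missing.
    """

    shells: np.ndarray
    relative: bool
    median: pd.DataFrame       # index: day, columns: shell index
    normalized: pd.DataFrame
    undefined: pd.DataFrame
    counts: Dict[Tuple[int, int], List[float]] = field(default_factory=dict)


def _loop_shell_counts(bc1: Barcode, edges: np.ndarray,
                       relative: bool) -> np.ndarray:
    births = bc1.births(dim=1)
    if relative and bc1.end_value > 0:
        births = births / bc1.end_value
    idx = np.digitize(births, edges[1:-1], right=False)
    counts = np.zeros(len(edges) - 1, dtype=float)
    for i in idx:
        counts[i] += 1
    return counts


def shell_loop_profile(per_day: Mapping[int, Sequence[Tuple[Barcode, int]]],
                       n_shells: int = 10,
                       shell_edges: Optional[Sequence[float]] = None,
                       baseline_day: int = 0) -> ShellProfile:
    """Build the per-shell loop profile of a treatment group.

    Parameters
    ----------
    per_day:
        Mapping day -> list of ``(dim-1 barcode, n_segments)`` per tumor;
        barcodes must come from radial filtrations sharing the same center
        convention.
    n_shells:
        Number of equal-width shells of each filtration's own maximal
        radius (relative mode; the default, for cross-day comparability).
    shell_edges:
        Absolute shell boundaries in micrometers (fixed-width mode);
        overrides ``n_shells``.

    A loop is assigned to the shell containing its birth radius — the only
    radial coordinate a dimension-1 bar has, since all loop deaths sit at
    the final radius. Per-shell counts are divided by the tumor's segment
    count, the median is taken across tumors, and each shell is normalized
    by its day-``baseline_day`` value.
    """
    if shell_edges is not None:
        edges = np.asarray(shell_edges, dtype=float)
        relative = False
    else:
        edges = np.linspace(0.0, 1.0, n_shells + 1)
        relative = True
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("shell edges must be strictly increasing")
    days = sorted(per_day)
    med = {}
    for day in days:
        per_tumor = []
        for bc1, n_segments in per_day[day]:
            if n_segments < 1:
                raise ValueError("n_segments must be >= 1")
            counts = _loop_shell_counts(bc1, edges, relative)
            per_tumor.append(counts / n_segments)
        med[day] = np.median(np.array(per_tumor), axis=0)
    median = pd.DataFrame.from_dict(med, orient="index")
    median.index.name = "day"
    if baseline_day not in med:
        raise ValueError(f"baseline day {baseline_day} missing from profile")
    base = median.loc[baseline_day]
    undefined = pd.DataFrame(
        np.broadcast_to((base == 0).to_numpy() | base.isna().to_numpy(),
                        median.shape),
        index=median.index, columns=median.columns)
    normalized = median.divide(base.replace(0, np.nan), axis=1)
    return ShellProfile(shells=edges, relative=relative, median=median,
                        normalized=normalized, undefined=undefined)


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class TestResult:
    test: str
    groups: Tuple[str, ...]
    statistic: float
    p_value: float
    significant: bool


@dataclass
class StatReport:
    results: List[TestResult]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.test, "/".join(r.groups), r.statistic, r.p_value,
              r.significant) for r in self.results],
            columns=["test", "groups", "statistic", "p_value", "significant"])


def group_tests(df: pd.DataFrame, value_col: str,
                group_col: str = "group", control: str = "control",
                alpha: float = 0.05) -> StatReport:
    """Kruskal-Wallis across groups plus pairwise Wilcoxon rank-sum tests
    of each treatment group against control (two-sided, exact where
    feasible, level ``alpha``, no multiple-testing correction)."""
    names = sorted(df[group_col].unique())
    samples = {g: df.loc[df[group_col] == g, value_col].dropna().to_numpy()
               for g in names}
    if len(names) < 2 or any(len(s) < 2 for s in samples.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    results: List[TestResult] = []
    stat, p = stats.kruskal(*[samples[g] for g in names])
    results.append(TestResult("kruskal-wallis", tuple(names), float(stat),
                              float(p), bool(p < alpha)))
    if control in samples:
        for g in names:
            if g == control:
                continue
            stat, p = stats.mannwhitneyu(samples[g], samples[control],
                                         alternative="two-sided",
                                         method="auto")
            results.append(TestResult("wilcoxon-rank-sum", (g, control),
                                      float(stat), float(p),
                                      bool(p < alpha)))
    return StatReport(results=results, alpha=alpha)


def wilcoxon_exact_enumeration(x: Sequence[float],
                               y: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Enumerates all rank assignments (feasible for n <= ~8 per group);
    serves as the independent oracle for the exact small-sample path of
    :func:`group_tests`. Assumes no ties.
    """
    from itertools import combinations

    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("enumeration oracle assumes no ties")
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:len(x)].sum()
    n, m = len(x), len(y)
    sums = [sum(c) for c in combinations(ranks, n)]
    sums = np.array(sums)
    mean = sums.mean()
    # two-sided: total probability of rank sums at least as extreme
    extreme = np.abs(sums - mean) >= abs(w_obs - mean) - 1e-9
    return float(extreme.sum() / len(sums))


# ---------------------------------------------------------------------------
# descriptor correlations


@dataclass
class CorrelationReport:
    corr: pd.DataFrame
    linkage: np.ndarray
    leaf_order: List[str]


def correlation_heatmap(df: pd.DataFrame) -> CorrelationReport:
    """Pairwise Pearson correlations between descriptor columns, with
    complete-linkage hierarchical clustering of the correlation-matrix rows
    under the Euclidean distance. Columns are ordered by name first so the
    leaf order is deterministic under ties."""
    cols = sorted(df.columns)
    data = df[cols].astype(float)
    corr = data.corr(method="pearson")
    if len(cols) < 2:
        raise ValueError("need >= 2 descriptor columns")
    link = hierarchy.linkage(corr.to_numpy(), method="complete",
                             metric="euclidean")
    order = hierarchy.leaves_list(link)
    return CorrelationReport(corr=corr, linkage=link,
                             leaf_order=[cols[i] for i in order])


def plot_correlation_heatmap(report: CorrelationReport, path) -> None:
    """Save the clustered correlation matrix as a figure (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = report.leaf_order
    mat = report.corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(order),
                                    1 + 0.5 * len(order)))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline helpers


def radial_descriptor_row(net: VesselNetwork, n_steps: int = 500,
                          short_fraction: float = 0.1) -> Dict[str, float]:
    """Radial-filtration descriptors of one network as a flat dict."""
    filt = radial_filtration(net, n_steps=n_steps)
    bc0, bc1 = persist_graph(filt)
    ds = compute_all(net, bc0=bc0, bc1=bc1, short_fraction=short_fraction)
    return ds.to_dict()


def descriptor_table(cohort: pd.DataFrame, n_steps: int = 500,
                     short_fraction: float = 0.1) -> pd.DataFrame:
    """Descriptor table of a cohort frame (columns group/day/subject/network).

    Runs the radial filtration pipeline on every network and returns one
    row per (group, day, subject) with all scalar descriptors.
    """
    rows = []
    for rec in cohort.itertuples():
        row = {"group": rec.group, "day": rec.day, "subject": rec.subject}
        row.update(radial_descriptor_row(rec.network, n_steps=n_steps,
                                         short_fraction=short_fraction))
        rows.append(row)
    return pd.DataFrame(rows)
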