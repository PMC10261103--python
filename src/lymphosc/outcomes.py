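"""Differential expression, exhaustion-score comparisons, and
signature-score survival stratification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .programs import score_signature
from .qcnorm import NormalizedMatrix

__all__ = [
    "DEGTable",
    "SurvivalDataset",
    "CutpointResult",
    "deg_wilcoxon",
    "exhaustion_scores",
    "optimal_cutpoint",
    "km_logrank",
    "logrank_statistic",
    "load_survival",
]


@dataclass
class DEGTable:
    table: pd.DataFrame  # gene, log2_fc, fold_change, p_value, adj_p, passed

    @property
    def passed(self) -> pd.DataFrame:
        return self.table[self.table["passed"]]


@dataclass
class SurvivalDataset:
    data: pd.DataFrame  # patient_id, time, event, score

    def __post_init__(self) -> None:
        required = {"patient_id", "time", "event", "score"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table lacks columns: {sorted(missing)}")
        if self.data[list(required)].isna().any().any():
            raise ValueError("survival table contains missing values")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # |standardized log-rank| at the cutpoint
    chi2: float
    group_sizes: tuple[int, int]  # (low, high)
    minprop: float


def load_survival(path) -> SurvivalDataset:
    return SurvivalDataset(pd.read_csv(path))


# ---------------------------------------------------------------------------
# differential expression


def deg_wilcoxon(
    nm: NormalizedMatrix | np.ndarray,
    group_a,
    group_b,
    gene_ids=None,
    adj_p: float = 0.01,
    min_fc: float = 1.5,
    eps: float = 1e-9,
) -> DEGTable:
    """Per-gene two-sided Mann-Whitney U between two cell groups.

    ``group_a``/``group_b`` are column index arrays or boolean masks.  The
    asymptotic normal approximation with tie and continuity correction is
    used.  Fold change is the ratio of de-logged group means
    (``expm1``) with an ``eps`` guard; p-values are Benjamini-Hochberg
    adjusted over all tested genes.  ``passed`` is
    ``adj_p <= threshold and fold_change >= min_fc``.
    """
    if isinstance(nm, NormalizedMatrix):
        values, gene_ids = nm.values, nm.gene_ids
    else:
        values = np.asarray(nm, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(values.shape[0])]
    a = values[:, np.asarray(group_a)]
    b = values[:, np.asarray(group_b)]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both groups must be nonempty")
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("both groups need >= 3 cells")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
    pvals = np.nan_to_num(np.atleast_1d(res.pvalue), nan=1.0)
    fc = (np.expm1(a).mean(axis=1) + eps) / (np.expm1(b).mean(axis=1) + eps)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "log2_fc": np.log2(fc),
            "fold_change": fc,
            "p_value": pvals,
            "adj_p": adj,
            "passed": (adj <= adj_p) & (fc >= min_fc),
        }
    )
    return DEGTable(table)


def exhaustion_scores(
    nm: NormalizedMatrix,
    exhaustion_set,
    groups: pd.Series | None = None,
    seed: int = 0,
    min_group: int = 3,
):
    """Signature scores per cell plus pairwise rank-sum tests between groups.

    Returns ``(scores, tests)`` where tests is a DataFrame with columns
    group_a, group_b, p_value (empty when < 2 usable groups).
    """
    sv = score_signature(nm, exhaustion_set, seed=seed, signature_name="exhaustion")
    tests = pd.DataFrame(columns=["group_a", "group_b", "p_value"])
    if groups is None:
        return sv, tests
    groups = groups.reindex(sv.scores.index)
    usable = []
    for g, grp in sv.scores.groupby(groups):
        if len(grp) < min_group:
            warnings.warn(f"group {g!r} has {len(grp)} cells (< {min_group}); excluded", stacklevel=2)
        else:
            usable.append(g)
    rows = []
    for ga, gb in combinations(usable, 2):
        p = scipy.stats.mannwhitneyu(
            sv.scores[groups == ga], sv.scores[groups == gb], alternative="two-sided"
        ).pvalue
        rows.append({"group_a": ga, "group_b": gb, "p_value": float(p)})
    if rows:
        tests = pd.DataFrame(rows)
    return sv, tests


# ---------------------------------------------------------------------------
# survival


def logrank_statistic(time, event, group) -> tuple[float, float, float]:
    """Two-group log-rank; returns (O1 - E1, variance, chi2).

    ``group`` is a boolean array marking arm 1.  Standard product of the
    hypergeometric moments at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o_minus_e**2) / var if var > 0 else 0.0
    return float(o_minus_e), float(var), float(chi2)


def optimal_cutpoint(d: SurvivalDataset, minprop: float = 0.3) -> CutpointResult:
    """Maximally selected rank statistic cutpoint.

    Candidates are midpoints of consecutive sorted unique scores; only
    candidates leaving at least ``minprop`` of patients on each side are
    admissible.  The candidate maximizing the absolute standardized log-rank
    statistic between {score > c} and {score <= c} wins; ties go to the
    smallest cutpoint.
    """
    df = d.data
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    uniq = np.unique(df["score"].to_numpy())
    if len(uniq) < 2:
        raise ValueError("scores are constant; no candidate cutpoint")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(df)
    time = df["time"].to_numpy()
    event = df["event"].to_numpy()
    score = df["score"].to_numpy()
    best = None
    for c in candidates:
        high = score > c
        n_high = int(high.sum())
        if min(n_high, n - n_high) / n < minprop:
            continue
        ome, var, _ = logrank_statistic(time, event, high)
        z = abs(ome) / np.sqrt(var) if var > 0 else 0.0
        if best is None or z > best[1] + 1e-12:
            best = (c, z, n_high)
    if best is None:
        raise ValueError(f"no candidate cutpoint satisfies minprop={minprop}")
    c, z, n_high = best
    return CutpointResult(
        cutpoint=float(c),
        statistic=float(z),
        chi2=float(z**2),
        group_sizes=(n - n_high, n_high),
        minprop=float(minprop),
    )


def km_logrank(d: SurvivalDataset, cutpoint: float):
    """Kaplan-Meier curves per arm plus the two-group log-rank test.

    Returns a dict with per-arm KM step functions (DataFrames with columns
    time, survival), the chi-squared statistic (1 df) and its p-value.
    """
    from lifelines import KaplanMeierFitter

    df = d.data
    high = df["score"].to_numpy() > cutpoint
    if high.all() or not high.any():
        raise ValueError("cutpoint leaves an empty arm")
    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        sub = df[mask]
        if sub["event"].sum() == 0:
            warnings.warn(f"arm {name!r} has zero events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    _, _, chi2 = logrank_statistic(df["time"], df["event"], high)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return {"curves": curves, "chi2": float(chi2), "p_value": p}
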