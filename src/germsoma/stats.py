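"""Summary statistics and hypothesis tests for cell-class censuses.

A cell's *workload* is the FML-weighted count of its function performances,

    workload = sum_j n_j * (m_j / m_base),

where ``n_j`` is the number of times function ``j`` was performed, ``m_j``
its function mutagen level, and ``m_base`` the base FML (the mutagen level
of NAND).  NOT is always non-mutagenic (``m_NOT = 0``) and contributes
nothing, so under a standard treatment (all non-NOT FMLs equal) the workload
is simply the number of mutagenic functions performed.

The *propagule workload difference* is the mean workload of the
propagule-ineligible cells minus the mean workload of the propagule-eligible
cells; a cell population counts as soma when ineligible cells exist and this
difference is positive (they perform a disproportionate share of the
mutagenic work).

Group comparisons use the Wilcoxon/Mann-Whitney rank-sum test (U convention:
``U = n_x * n_y`` at complete separation, mid-ranks for ties) with Holm
step-down adjustment for multiple comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .machine import FUNCTION_NAMES, N_FUNCTIONS

__all__ = [
    "workload_weights",
    "workload",
    "propagule_workload_difference",
    "class_shares",
    "classify_soma",
    "rank_sum_test",
    "holm_adjust",
    "treatment_summary",
]

_COUNT_COLS = [f"n_{f}" for f in FUNCTION_NAMES]


def workload_weights(fml_table, base_fml: float | None = None) -> np.ndarray:
    """Per-function workload weights ``m_j / m_base``.

    When the base FML is zero (the all-zero-FML control) the weights degrade
    to 1 for every non-NOT function, so the workload becomes a plain count of
    non-NOT performances.
    """
    fml = np.asarray(fml_table, dtype=float)
    if fml.shape != (N_FUNCTIONS,):
        raise ValueError("fml table must have 9 entries")
    if base_fml is None:
        base_fml = float(fml[FUNCTION_NAMES.index("NAND")])
    if base_fml > 0:
        return fml / base_fml
    w = np.ones(N_FUNCTIONS)
    w[FUNCTION_NAMES.index("NOT")] = 0.0
    return w


def workload(counts, fml_table, base_fml: float | None = None) -> float:
    """FML-weighted performance count of a single cell."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_FUNCTIONS,):
        raise ValueError("counts must have 9 entries")
    if np.any(counts < 0):
        raise ValueError("performance counts must be non-negative")
    return float(counts @ workload_weights(fml_table, base_fml))


def _census_workloads(census: pd.DataFrame, fml_table=None,
                      base_fml: float | None = None) -> pd.Series:
    if len(census) == 0:
        raise ValueError("census is empty")
    if fml_table is None:
        if "workload" not in census.columns:
            raise ValueError("census lacks a workload column and no FML table given")
        return census["workload"]
    w = workload_weights(fml_table, base_fml)
    return pd.Series(census[_COUNT_COLS].to_numpy(dtype=float) @ w,
                     index=census.index)


def propagule_workload_difference(census: pd.DataFrame, fml_table=None,
                                  base_fml: float | None = None) -> float:
    """Mean workload of ineligible cells minus mean workload of eligible cells.

    NaN (a flag, not an exception) when either class is absent.
    """
    wl = _census_workloads(census, fml_table, base_fml)
    elig = census["eligible"].astype(bool)
    if elig.all() or (~elig).all():
        return float("nan")
    return float(wl[~elig].mean() - wl[elig].mean())


def class_shares(census: pd.DataFrame, fml_table=None,
                 base_fml: float | None = None) -> tuple[float, float]:
    """(proportion of ineligible cells, ineligible share of total workload).

    The share is NaN when no work has been performed at all (0/0).
    """
    wl = _census_workloads(census, fml_table, base_fml)
    elig = census["eligible"].astype(bool)
    prop = float((~elig).mean())
    total = float(wl.sum())
    share = float(wl[~elig].sum() / total) if total > 0 else float("nan")
    return prop, share


def classify_soma(census: pd.DataFrame, fml_table=None,
                  base_fml: float | None = None) -> bool:
    """True iff ineligible cells exist and out-work the eligible cells.

    Guards against pseudo-classification: rare ineligible cells produced by
    disruptive mutations have *negative* workload difference and do not count.
    """
    if len(census) == 0:
        raise ValueError("census is empty")
    diff = propagule_workload_difference(census, fml_table, base_fml)
    return bool(not np.isnan(diff) and diff > 0)


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where U counts pairs in which x exceeds y (ties 1/2),
    so ``U = n_x * n_y`` at complete separation of x over y.  The p-value is
    exact for small tie-free samples (``n_x * n_y <= 400``) and uses the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return u, float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def treatment_summary(census: pd.DataFrame, group_by: str = "treatment",
                      fml_table=None, base_fml: float | None = None) -> pd.DataFrame:
    """Per-treatment summary table: proportion of ineligible cells and the
    propagule workload difference, with means +/- standard errors across
    replicates (column ``replicate`` when present, else one group)."""
    rows = []
    for name, grp in census.groupby(group_by):
        reps = grp.groupby("replicate") if "replicate" in grp.columns else [(0, grp)]
        props, diffs = [], []
        for _, rep in reps:
            p, _ = class_shares(rep, fml_table, base_fml)
            props.append(p)
            diffs.append(propagule_workload_difference(rep, fml_table, base_fml))
        props = np.array(props)
        diffs = np.array(diffs)

        def _se(v):
            v = v[~np.isnan(v)]
            return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

        rows.append({
            group_by: name,
            "n_replicates": len(props),
            "prop_ineligible_mean": float(np.nanmean(props)),
            "prop_ineligible_se": _se(props),
            "workload_difference_mean": float(np.nanmean(diffs))
            if not np.all(np.isnan(diffs)) else float("nan"),
            "workload_difference_se": _se(diffs),
        })
    return pd.DataFrame(rows)
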