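"""Group statistics: mean +/- SEM and the Mann-Whitney U test.

U is computed from midrank sums; the p-value is exact when
min(n, m) <= 8 and there are no ties, otherwise a tie-corrected normal
approximation (with continuity correction) is used.  Two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from fibroquant.exceptions import ParameterError

EXACT_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u_a: float  # U statistic oriented on the first group
    u_b: float  # n*m - u_a
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(values_a, values_b) -> MannWhitneyResult:
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("non-finite values in group data")
    n, m = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    u_b = float(n * m - u_a)
    has_ties = np.unique(np.concatenate([a, b])).size < n + m
    if min(n, m) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u_a=u_a, u_b=u_b, p_value=float(res.pvalue), method=method)


def sem(values) -> float:
    """Standard error of the mean, sd/sqrt(n) with sample sd (ddof=1)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass(frozen=True)
class GroupComparison:
    readout: str
    timepoint: str | None
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    u_statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "readout", "timepoint", "group_a", "group_b", "n_a", "n_b",
            "mean_a", "mean_b", "sem_a", "sem_b", "u_statistic", "p_value", "method",
        )}


DEFAULT_READOUTS = (
    "fibrotic_mass_percent",
    "alveolar_collagen_percent",
    "total_collagen_percent",
)


def compare_groups(
    table: pd.DataFrame,
    readouts=DEFAULT_READOUTS,
    group_col: str = "group",
    timepoint_col: str | None = None,
    qc_col: str = "qc_excluded",
    exclude_qc: bool = True,
) -> list[GroupComparison]:
    """Pairwise Mann-Whitney comparisons per readout (and timepoint).

    QC-excluded rows are dropped before computing group n, means and SEMs.
    """
    df = table.copy()
    if exclude_qc and qc_col in df.columns:
        df = df[~df[qc_col].astype(bool)]
    if timepoint_col is not None:
        strata = [(tp, sub) for tp, sub in df.groupby(timepoint_col)]
    else:
        strata = [(None, df)]

    out: list[GroupComparison] = []
    for tp, sub in strata:
        groups = list(dict.fromkeys(sub[group_col]))
        if len(groups) < 2:
            raise ParameterError(
                f"need >= 2 groups after QC exclusion, got {groups} (timepoint={tp})"
            )
        for ga, gb in combinations(groups, 2):
            for readout in readouts:
                if readout not in sub.columns:
                    continue
                va = sub.loc[sub[group_col] == ga, readout].dropna().to_numpy(float)
                vb = sub.loc[sub[group_col] == gb, readout].dropna().to_numpy(float)
                if va.size == 0 or vb.size == 0:
                    continue
                mw = mann_whitney(va, vb)
                out.append(
                    GroupComparison(
                        readout=readout, timepoint=tp, group_a=ga, group_b=gb,
                        n_a=va.size, n_b=vb.size,
                        mean_a=float(va.mean()), mean_b=float(vb.mean()),
                        sem_a=sem(va), sem_b=sem(vb),
                        u_statistic=mw.u_a, p_value=mw.p_value, method=mw.method,
                    )
                )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


def t_test(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-sided t-test (secondary to Mann-Whitney)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test needs n >= 2 per group")
    res = sps.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default downstream)."""
    p = np.asarray(p_values, dtype=np.float64)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    k = p.size
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
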