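"""Population-level radial profiles and position classification.

Per-nucleus shell signals are aggregated into a mean ± SEM profile per
condition, conditions are compared shell-by-shell (Welch t-tests, with
one-way ANOVA as the omnibus test for more than two groups), and a
territory's radial position is called *interior*, *intermediate* or
*peripheral* from the weighted mean shell index

    m = sum_i i * n_i / sum_i n_i,

the signal-weighted average shell number (1 = innermost).  A uniform profile
gives m = (k+1)/2; for five shells the default category cuts are m <= 2.6
(interior) and m >= 3.4 (peripheral), symmetric about 3 and scaled as
(k+1)/2 -/+ 0.4*(k-1)/4 for other shell counts.  The numeric rule is this
package's operationalization of the categorical call; the thresholds used
are recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .shells import ShellSignal

__all__ = [
    "RadialProfile",
    "PositionCall",
    "aggregate",
    "compare_conditions",
    "anova_by_shell",
    "weighted_shell_index",
    "classify_position",
    "classify_nuclei",
    "position_frequency",
    "default_thresholds",
]

CATEGORIES = ("interior", "intermediate", "peripheral")


@dataclass
class RadialProfile:
    """Mean ± SEM normalized shell profile over a population of nuclei."""

    condition: str
    k: int
    mean_n: tuple[float, ...]
    sem_n: tuple[float, ...]
    n_nuclei: int


@dataclass
class PositionCall:
    """Categorical radial position with its weighted-mean-shell statistic."""

    category: str
    m: float
    thresholds: tuple[float, float]


def _signal_matrix(signals: list[ShellSignal]) -> np.ndarray:
    if not signals:
        raise ValueError("empty signal list")
    k = signals[0].k
    if any(s.k != k for s in signals):
        raise ValueError("signals have mixed shell counts")
    return np.array([s.n for s in signals], dtype=float)


def aggregate(signals: list[ShellSignal], condition: str = "") -> RadialProfile:
    """Per-shell mean and SEM of the normalized ratio across nuclei.

    SEM is the sample standard deviation (ddof=1) over nuclei divided by
    sqrt(n); a single nucleus yields SEM 0.
    """
    mat = _signal_matrix(signals)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    return RadialProfile(condition, mat.shape[1], tuple(mean.tolist()), tuple(sem.tolist()), n)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # degenerate cases scipy reports as nan: zero variance in both groups
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def compare_conditions(
    a: list[ShellSignal],
    b: list[ShellSignal],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Shell-by-shell two-sample comparison of normalized signals.

    Runs a two-tailed Welch (unequal-variance) t-test on ``n_x`` across
    nuclei for every shell.  No multiple-testing correction is applied by
    default; ``correction="holm"`` adjusts the per-shell p-values
    (Holm step-down) before flagging.

    Returns a DataFrame with columns shell, t, p, flag (p <= alpha).
    """
    ma, mb = _signal_matrix(a), _signal_matrix(b)
    if ma.shape[1] != mb.shape[1]:
        raise ValueError("conditions have different shell counts")
    if ma.shape[0] < 2 or mb.shape[0] < 2:
        raise InsufficientDataError("need at least 2 nuclei per condition")
    rows = [(_welch(ma[:, i], mb[:, i])) for i in range(ma.shape[1])]
    df = pd.DataFrame(rows, columns=["t", "p"])
    df.insert(0, "shell", np.arange(1, ma.shape[1] + 1))
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        df["p"] = multipletests(df["p"], method="holm")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    df["flag"] = df["p"] <= alpha
    return df


def anova_by_shell(groups: list[list[ShellSignal]]) -> pd.DataFrame:
    """One-way ANOVA per shell across two or more conditions."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two conditions")
    mats = [_signal_matrix(g) for g in groups]
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValueError("conditions have different shell counts")
    if any(m.shape[0] < 2 for m in mats):
        raise InsufficientDataError("need at least 2 nuclei per condition")
    rows = []
    for i in range(k):
        samples = [m[:, i] for m in mats]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            rows.append((0.0, 1.0))
        else:
            f, p = stats.f_oneway(*samples)
            rows.append((float(f), float(p)))
    df = pd.DataFrame(rows, columns=["F", "p"])
    df.insert(0, "shell", np.arange(1, k + 1))
    return df


def default_thresholds(k: int) -> tuple[float, float]:
    """Category cuts symmetric about the uniform-profile value (k+1)/2.

    For k=5 these are (2.6, 3.4); for other k the half-width 0.4 scales with
    (k-1)/4 so the cuts keep the same relative position between the centre
    and the extreme shells.
    """
    center = (k + 1) / 2.0
    half = 0.4 * (k - 1) / 4.0
    return center - half, center + half


def weighted_shell_index(n_values) -> float:
    """Signal-weighted mean shell number of a normalized profile."""
    n = np.asarray(n_values, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("profile is all zero; weighted shell index undefined")
    i = np.arange(1, n.size + 1)
    return float((i * n).sum() / total)


def classify_position(
    profile: RadialProfile, thresholds: tuple[float, float] | None = None
) -> PositionCall:
    """Call a population profile interior / intermediate / peripheral."""
    if profile.k < 2:
        raise ValueError("classification requires at least 2 shells")
    t_lo, t_hi = thresholds if thresholds is not None else default_thresholds(profile.k)
    m = weighted_shell_index(profile.mean_n)
    if m <= t_lo:
        category = "interior"
    elif m >= t_hi:
        category = "peripheral"
    else:
        category = "intermediate"
    return PositionCall(category, m, (t_lo, t_hi))


def classify_nuclei(
    signals: list[ShellSignal], thresholds: tuple[float, float] | None = None
) -> list[PositionCall]:
    """Per-nucleus position calls (one call per shell signal)."""
    calls = []
    for s in signals:
        prof = RadialProfile("", s.k, s.n, (0.0,) * s.k, 1)
        calls.append(classify_position(prof, thresholds))
    return calls


def position_frequency(calls_by_condition: dict[str, list[PositionCall]]):
    """Tally per-nucleus calls by condition and test homogeneity.

    Returns ``(table, pairwise)``: a DataFrame of counts and percentages per
    condition over the three categories, and a DataFrame of pairwise
    chi-square homogeneity tests on the 2×3 count tables.  A warning column
    marks comparisons with expected counts below 5.
    """
    if len(calls_by_condition) < 2:
        raise ValueError("need at least two conditions")
    rows = {}
    for cond, calls in calls_by_condition.items():
        if not calls:
            raise ValueError(f"condition {cond!r} has no calls")
        counts = [sum(c.category == cat for c in calls) for cat in CATEGORIES]
        rows[cond] = counts
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    pct = 100.0 * table.div(table.sum(axis=1), axis=0)
    table = table.join(pct, rsuffix="_pct")

    conds = list(rows)
    pair_rows = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            obs = np.array([rows[conds[i]], rows[conds[j]]])
            obs_t = obs[:, obs.sum(axis=0) > 0]  # drop empty categories
            if obs_t.shape[1] < 2 or np.array_equal(obs[0], obs[1]):
                chi2, p, expected = 0.0, 1.0, obs_t
            else:
                chi2, p, _, expected = stats.chi2_contingency(obs_t)
            pair_rows.append(
                {
                    "condition_a": conds[i],
                    "condition_b": conds[j],
                    "chi2": float(chi2),
                    "p": float(p),
                    "low_expected": bool(np.any(np.asarray(expected) < 5)),
                }
            )
    return table, pd.DataFrame(pair_rows)
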