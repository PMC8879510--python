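"""C-start response scoring and phenotype comparisons.

A trial counts as a response iff a latency is recorded and it falls within
the gate (default 25 ms, inclusive: the C-bend must begin within 25 ms of
the stimulus). Rates are per fish (responses / trials delivered); the fish
is the independent statistical unit, so group comparisons run on per-fish
rates. Welch's t is the default; a label-permutation test and a
pooled-trial chi-square (sensitivity analysis) are available.

AM1-43 staining intensities and hair-cell counts arrive as plain numeric
samples; intensity is summarised as percent of control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseSummary",
    "GroupComparison",
    "IntensityResult",
    "CountResult",
    "score_trials",
    "score_all_groups",
    "compare_groups",
    "relative_intensity",
    "count_summary",
]

DEFAULT_LATENCY_CUTOFF_MS = 25.0


@dataclass(frozen=True)
class ResponseSummary:
    """Per-fish response rates for one group."""

    group: str
    fish_ids: tuple[str, ...]
    per_fish_rate: tuple[float, ...]  # responses / trials, in [0, 1]
    n_trials: tuple[int, ...]
    n_responses: tuple[int, ...]

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def group_mean_rate(self) -> float:
        """Mean per-fish rate, as a percentage."""
        return 100.0 * float(np.mean(self.per_fish_rate))


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test_name: str
    n_a: int
    n_b: int
    effect: float  # difference of group means (a - b); percentage points for rates


@dataclass(frozen=True)
class IntensityResult:
    percent_of_control: float
    mean_mut: float
    mean_wt: float
    comparison: GroupComparison


@dataclass(frozen=True)
class CountResult:
    mean_mut: float
    mean_wt: float
    comparison: GroupComparison
    low_n: bool


def score_trials(
    trials: pd.DataFrame,
    latency_cutoff_ms: float = DEFAULT_LATENCY_CUTOFF_MS,
    group: Optional[str] = None,
) -> ResponseSummary:
    """Score a trial table for one group.

    ``trials`` needs columns fish_id, trial_index, latency_ms (NaN/empty =
    no response) and optionally group. A response is latency present and
    <= cutoff. Fish with zero trials are excluded with a warning.
    """
    if latency_cutoff_ms <= 0:
        raise ValueError("latency_cutoff_ms must be positive")
    df = trials
    if "group" in df.columns:
        groups = df["group"].unique().tolist()
        if group is not None:
            df = df[df["group"] == group]
            if df.empty:
                raise ValueError(f"no trials for group {group!r}")
        elif len(groups) > 1:
            raise ValueError(
                f"table mixes groups {groups}; pass group= or use score_all_groups"
            )
        else:
            group = str(groups[0])
    label = group if group is not None else "all"

    fish_ids, rates, n_trials, n_resp = [], [], [], []
    for fish, sub in df.groupby("fish_id", sort=True):
        total = len(sub)
        if total == 0:  # defensive; groupby never yields empty groups
            warnings.warn(f"fish {fish!r} has zero trials; excluded")
            continue
        responses = int(
            (sub["latency_ms"].notna() & (sub["latency_ms"] <= latency_cutoff_ms)).sum()
        )
        fish_ids.append(str(fish))
        rates.append(responses / total)
        n_trials.append(total)
        n_resp.append(responses)
    if not fish_ids:
        raise ValueError("no fish with trials in the table")
    return ResponseSummary(
        group=label,
        fish_ids=tuple(fish_ids),
        per_fish_rate=tuple(rates),
        n_trials=tuple(n_trials),
        n_responses=tuple(n_resp),
    )


def score_all_groups(
    trials: pd.DataFrame, latency_cutoff_ms: float = DEFAULT_LATENCY_CUTOFF_MS
) -> dict[str, ResponseSummary]:
    """Score every group in a mixed trial table."""
    if "group" not in trials.columns:
        return {"all": score_trials(trials, latency_cutoff_ms)}
    return {
        str(g): score_trials(trials, latency_cutoff_ms, group=str(g))
        for g in trials["group"].unique()
    }


def _rates(x: Union[ResponseSummary, Sequence[float]]) -> np.ndarray:
    if isinstance(x, ResponseSummary):
        return np.asarray(x.per_fish_rate, dtype=float)
    return np.asarray(x, dtype=float)


def compare_groups(
    summary_a: Union[ResponseSummary, Sequence[float]],
    summary_b: Union[ResponseSummary, Sequence[float]],
    method: str = "welch_t",
    n_perm: int = 10000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> GroupComparison:
    """Compare two groups of per-fish response rates.

    Methods: ``welch_t`` (default), ``student_t``, ``permutation``
    (two-sided label permutation of per-fish rates with +1 smoothing),
    ``pooled_chi2`` (trials pooled into a 2x2 table; requires
    ResponseSummary inputs). Effect is the difference of group mean rates
    in percentage points (a - b).
    """
    a, b = _rates(summary_a), _rates(summary_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two fish per group")
    effect = 100.0 * (float(np.mean(a)) - float(np.mean(b)))
    degenerate = np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b)

    if method in ("welch_t", "student_t"):
        if degenerate:
            return GroupComparison(0.0, 1.0, method, len(a), len(b), effect)
        res = stats.ttest_ind(a, b, equal_var=(method == "student_t"))
        return GroupComparison(
            float(res.statistic), float(res.pvalue), method, len(a), len(b), effect
        )
    if method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        observed = abs(np.mean(a) - np.mean(b))
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            diff = abs(np.mean(pooled[: len(a)]) - np.mean(pooled[len(a):]))
            if diff >= observed - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        return GroupComparison(observed, p, method, len(a), len(b), effect)
    if method == "pooled_chi2":
        if not (
            isinstance(summary_a, ResponseSummary)
            and isinstance(summary_b, ResponseSummary)
        ):
            raise ValueError("pooled_chi2 needs ResponseSummary inputs (trial counts)")
        table = np.array(
            [
                [sum(summary_a.n_responses),
                 sum(summary_a.n_trials) - sum(summary_a.n_responses)],
                [sum(summary_b.n_responses),
                 sum(summary_b.n_trials) - sum(summary_b.n_responses)],
            ]
        )
        res = stats.chi2_contingency(table)
        return GroupComparison(
            float(res.statistic), float(res.pvalue), method, len(a), len(b), effect
        )
    raise ValueError(f"unknown method {method!r}")


def relative_intensity(
    values_mut: Sequence[float], values_wt: Sequence[float]
) -> IntensityResult:
    """Mutant staining intensity as percent of control, plus a Welch t-test
    on the raw values."""
    mut = np.asarray(values_mut, dtype=float)
    wt = np.asarray(values_wt, dtype=float)
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.mean(wt) == 0:
        raise ValueError("control mean is zero; relative intensity undefined")
    pct = 100.0 * float(np.mean(mut)) / float(np.mean(wt))
    if mut.size >= 2 and wt.size >= 2 and not (np.var(mut) == 0 and np.var(wt) == 0):
        res = stats.ttest_ind(mut, wt, equal_var=False)
        comp = GroupComparison(
            float(res.statistic), float(res.pvalue), "welch_t",
            mut.size, wt.size, float(np.mean(mut) - np.mean(wt)),
        )
    else:
        p = 1.0 if np.mean(mut) == np.mean(wt) else float("nan")
        comp = GroupComparison(
            float("nan"), p, "welch_t", mut.size, wt.size,
            float(np.mean(mut) - np.mean(wt)),
        )
    return IntensityResult(
        percent_of_control=pct,
        mean_mut=float(np.mean(mut)),
        mean_wt=float(np.mean(wt)),
        comparison=comp,
    )


def count_summary(
    counts_mut: Sequence[float], counts_wt: Sequence[float]
) -> CountResult:
    """Group means (2 decimals) of integer-valued counts plus a Welch t."""
    mut = np.asarray(counts_mut, dtype=float)
    wt = np.asarray(counts_wt, dtype=float)
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(mut == np.rint(mut)) and np.all(wt == np.rint(wt))):
        raise ValueError("counts must be integer-valued")
    low_n = mut.size < 2 or wt.size < 2
    if not low_n and not (np.var(mut) == 0 and np.var(wt) == 0):
        res = stats.ttest_ind(mut, wt, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif not low_n:
        stat, p = 0.0, 1.0 if np.mean(mut) == np.mean(wt) else 0.0
    else:
        stat, p = float("nan"), float("nan")
    comp = GroupComparison(
        stat, p, "welch_t", mut.size, wt.size,
        float(np.mean(mut) - np.mean(wt)),
    )
    return CountResult(
        mean_mut=round(float(np.mean(mut)), 2),
        mean_wt=round(float(np.mean(wt)), 2),
        comparison=comp,
        low_n=low_n,
    )
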