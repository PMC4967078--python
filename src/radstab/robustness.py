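"""Robustness analysis of feature values across acquisition conditions.

The central statistic is the reproducibility-to-repeatability ratio

    Q(f; r) = S( f_r(Phi_i) - f_0(Phi_i) | i = 1..N )
              --------------------------------------
              S( f_0(Phi_i) - f_0(Phi_i') | i = 1..M )

where f_r / f_0 are the feature computed at condition r and at the reference
condition, Phi_i is a case's contour and Phi_i' its repeat contour, N is the
number of cases and M the number of cases with a repeat contour, and S is a
standard deviation (sample, n-1, by default).  A feature is considered robust
to condition r when Q(f; r) <= 1: the change induced by the condition is no
larger than the change induced by re-contouring the same reference image.

The module also provides per-condition feature summaries, nearest-condition
matching against the reference, and the feature/condition rankings (count of
Q <= 1, ties broken by descending max Q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionGrid",
    "QTable",
    "ZeroRepeatabilityError",
    "InsufficientObservationsError",
    "q_measure",
    "build_q_table",
    "condition_feature_summary",
    "nearest_condition",
    "nearest_condition_histogram",
    "rank_features",
    "rank_conditions",
]


class ZeroRepeatabilityError(RuntimeError):
    """The repeat-contour difference sample has zero spread."""


class InsufficientObservationsError(ValueError):
    """A (feature, condition) cell has fewer than two observations."""


@dataclass(frozen=True)
class ConditionGrid:
    """A set of acquisition/reconstruction condition labels with a reference."""

    conditions: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.conditions.count(self.reference) != 1:
            raise ValueError(f"reference {self.reference!r} must appear exactly once")

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.reference)

    def __len__(self) -> int:
        return len(self.conditions)


@dataclass
class QTable:
    """Q(f; r) for every feature and non-reference condition.

    ``data`` columns: family, feature, condition, q.  Entries whose
    repeatability denominator was zero are excluded from ``data`` and listed
    in ``excluded``.
    """

    data: pd.DataFrame
    n_cases: int
    n_repeat: int
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["family", "feature", "condition"])
    )

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_repeat < 2:
            raise ValueError("N and M must both be >= 2")
        if len(self.data) and (self.data["q"] < 0).any():
            raise ValueError("Q must be nonnegative")


def q_measure(
    ref_values: np.ndarray,
    cond_values: np.ndarray,
    repeat_ref: np.ndarray,
    ddof: int = 1,
) -> float:
    """Reproducibility-to-repeatability ratio for one feature and condition.

    Parameters
    ----------
    ref_values, cond_values : arrays of length N
        Feature at the reference and at condition r, per case, on the same
        contours in the same case order.
    repeat_ref : array of shape (M, 2)
        Feature at the reference on (original, repeat) contour pairs.
    ddof : int
        0 for the population, 1 (default) for the sample standard deviation.
    """
    ref_values = np.asarray(ref_values, dtype=float)
    cond_values = np.asarray(cond_values, dtype=float)
    repeat_ref = np.asarray(repeat_ref, dtype=float)
    if ref_values.shape != cond_values.shape or ref_values.ndim != 1:
        raise ValueError("ref_values and cond_values must be 1D of equal length")
    if ref_values.size < 2:
        raise ValueError("need N >= 2 cases")
    if repeat_ref.ndim != 2 or repeat_ref.shape[1] != 2 or repeat_ref.shape[0] < 2:
        raise ValueError("repeat_ref must be (M, 2) with M >= 2")
    num = float(np.std(cond_values - ref_values, ddof=ddof))
    den = float(np.std(repeat_ref[:, 0] - repeat_ref[:, 1], ddof=ddof))
    if den == 0:
        raise ZeroRepeatabilityError("repeat-contour differences have zero spread")
    return num / den


def build_q_table(
    table: pd.DataFrame,
    grid: ConditionGrid,
    ddof: int = 1,
) -> QTable:
    """Compute Q(f; r) for every (family, feature) and non-reference condition.

    ``table`` is a long-form feature table with columns case_id, condition,
    contour_id, family, feature, value.  The numerator uses all cases present
    at both the reference and the condition (contour "orig"); the denominator
    uses the cases that carry a "repeat" contour at the reference.
    """
    ref = grid.reference
    orig = table[table["contour_id"] == "orig"]
    rep = table[(table["contour_id"] == "repeat") & (table["condition"] == ref)]
    rows = []
    excluded = []
    piv = orig.pivot_table(
        index=["family", "feature", "case_id"],
        columns="condition",
        values="value",
        aggfunc="first",
    )
    rep_piv = rep.pivot_table(
        index=["family", "feature", "case_id"], values="value", aggfunc="first"
    )
    n_cases = orig["case_id"].nunique()
    n_repeat = rep["case_id"].nunique()
    for (family, feature), block in piv.groupby(level=["family", "feature"]):
        block = block.droplevel(["family", "feature"])
        f0 = block[ref]
        try:
            rep_vals = rep_piv.loc[(family, feature)]["value"]
        except KeyError as exc:
            raise InsufficientObservationsError(
                f"no repeat contours for ({family}, {feature})"
            ) from exc
        pair_cases = rep_vals.index.intersection(f0.index)
        pairs = np.column_stack(
            [f0.loc[pair_cases].to_numpy(), rep_vals.loc[pair_cases].to_numpy()]
        )
        for cond in grid.non_reference:
            fr = block[cond]
            try:
                q = q_measure(f0.to_numpy(), fr.to_numpy(), pairs, ddof=ddof)
            except ZeroRepeatabilityError:
                excluded.append((family, feature, cond))
                continue
            rows.append((family, feature, cond, q))
    data = pd.DataFrame(rows, columns=["family", "feature", "condition", "q"])
    excl = pd.DataFrame(excluded, columns=["family", "feature", "condition"])
    return QTable(data=data, n_cases=n_cases, n_repeat=n_repeat, excluded=excl)


def condition_feature_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample std of every feature per condition, across ROIs/cases.

    Raises
    ------
    InsufficientObservationsError
        Listing any (feature, condition) cell with fewer than 2 observations.
    """
    orig = table[table["contour_id"] == "orig"]
    g = orig.groupby(["family", "feature", "condition"])["value"]
    summary = g.agg(mean="mean", std=lambda s: s.std(ddof=1), n="count").reset_index()
    bad = summary[summary["n"] < 2]
    if len(bad):
        pairs = [
            f"({r.family}/{r.feature}, {r.condition})" for r in bad.itertuples()
        ]
        raise InsufficientObservationsError(
            "fewer than 2 observations for: " + ", ".join(pairs)
        )
    return summary


def nearest_condition(
    summary: pd.DataFrame,
    family: str,
    feature: str,
    reference: str,
) -> str:
    """Non-reference condition whose mean feature value is nearest the reference.

    Ties are broken by condition label order, with a warning.
    """
    block = summary[(summary["family"] == family) & (summary["feature"] == feature)]
    means = block.set_index("condition")["mean"]
    if reference not in means.index:
        raise KeyError(f"reference condition {reference!r} missing for {feature!r}")
    others = means.drop(reference)
    if len(others) == 0:
        raise ValueError("need at least one non-reference condition")
    dist = (others - means[reference]).abs().sort_index()
    winners = dist.index[dist == dist.min()]
    if len(winners) > 1:
        warnings.warn(
            f"nearest-condition tie for ({family}, {feature}): {list(winners)}; "
            "taking first by label order",
            RuntimeWarning,
        )
    return str(winners[0])


def nearest_condition_histogram(
    summary: pd.DataFrame,
    reference: str,
) -> pd.Series:
    """How often each condition is the nearest match to the reference.

    Counts over all (family, feature) pairs in the summary; counts sum to the
    number of features.
    """
    feats = summary[["family", "feature"]].drop_duplicates()
    counts: dict[str, int] = {}
    for row in feats.itertuples():
        c = nearest_condition(summary, row.family, row.feature, reference)
        counts[c] = counts.get(c, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def _q_stats(g: pd.DataFrame) -> dict[str, float]:
    q = g["q"]
    return {
        "mean_q": q.mean(),
        "std_q": q.std(ddof=1) if len(q) > 1 else 0.0,
        "min_q": q.min(),
        "max_q": q.max(),
        "n_q_le_1": int((q <= 1).sum()),
        "max_condition": g.loc[q.idxmax(), "condition"],
    }


def rank_features(qtable: QTable) -> pd.DataFrame:
    """Rank features by robustness: count of conditions with Q <= 1.

    Sorted by count descending, then max Q descending, then family/feature
    label.  Each row carries mean/std/min/max Q and the condition attaining
    the max.
    """
    rows = []
    for (family, feature), g in qtable.data.groupby(["family", "feature"]):
        rows.append({"family": family, "feature": feature, **_q_stats(g)})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["n_q_le_1", "max_q", "family", "feature"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def rank_conditions(qtable: QTable) -> pd.DataFrame:
    """Rank conditions by how many features have Q <= 1 under them.

    Sorted by total count descending, ties by max Q descending, then label;
    per-family counts are included and sum to the total.
    """
    rows = []
    for cond, g in qtable.data.groupby("condition"):
        stats = _q_stats(g)
        stats.pop("max_condition")
        row = {"condition": cond, **stats}
        fam_counts = g[g["q"] <= 1].groupby("family").size()
        total = 0
        for fam in sorted(qtable.data["family"].unique()):
            base = fam.split(" ")[0]  # "GLCM(25) mean" -> "GLCM(25)"
            key = f"n_q_le_1[{base}]" if base != "Histogram" else "n_q_le_1[Histogram]"
            row[key] = row.get(key, 0) + int(fam_counts.get(fam, 0))
            total += int(fam_counts.get(fam, 0))
        row["n_q_le_1"] = total
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["n_q_le_1", "max_q", "condition"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
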