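"""Biomarker association and comparison statistics for screen scores.

All tests are reported uncorrected for multiple testing, matching the
screening-resource convention of flagging candidate associations rather
than controlling family-wise error; callers combining many markers
should correct downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AssociationResult",
    "FociExperiment",
    "mann_whitney_association",
    "spearman_drug_correlation",
    "sensitivity_ranks",
    "anova_curve_comparison",
    "foci_positive_fraction",
]


@dataclass(frozen=True)
class AssociationResult:
    drug_id: str
    marker: str
    group_sizes: tuple[int, int]
    u_statistic: float
    p_value: float
    direction: int  # sign of median(group1) - median(group0)


def mann_whitney_association(
    scores: Sequence[float],
    labels: Sequence,
    drug_id: str = "",
    marker: str = "",
) -> AssociationResult:
    """Two-sided Mann-Whitney U test of scores between two label groups.

    Uses the exact null distribution when min(n1, n2) <= 8 and the data
    are tie-free, and the tie-corrected normal approximation otherwise
    (no continuity correction, so exchangeable groups give p = 1). No
    multiple-testing correction is applied.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 label groups, got {levels}")
    g0 = scores[labels == levels[0]]
    g1 = scores[labels == levels[1]]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(scores).size < 2:
        raise ValueError("need at least 2 distinct score values")
    has_ties = np.unique(scores).size < scores.size
    if min(g0.size, g1.size) <= 8 and not has_ties:
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            g1, g0, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
    diff = float(np.median(g1) - np.median(g0))
    # report the classic U = min(U1, U2); scipy returns the first sample's U1
    u = float(min(res.statistic, g0.size * g1.size - res.statistic))
    return AssociationResult(
        drug_id=drug_id,
        marker=marker,
        group_sizes=(int(g0.size), int(g1.size)),
        u_statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        direction=int(np.sign(diff)),
    )


def spearman_drug_correlation(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) between paired drug scores.

    Incomplete pairs are dropped; needs >=3 complete pairs and nonzero
    rank variance on both sides. p comes from the t approximation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValueError(f"need >=3 complete pairs, got {a.size}")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("zero rank variance; Spearman rho undefined")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def sensitivity_ranks(z_scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Rank cell lines by sensitivity: rank 1 = lowest (most negative) Z.

    Ties share the minimum rank; missing scores stay unranked (NaN).
    """
    s = pd.Series(dict(z_scores) if not isinstance(z_scores, pd.Series) else z_scores,
                  dtype=float)
    if s.dropna().empty:
        raise ValueError("all scores missing; nothing to rank")
    return s.rank(method="min", ascending=True, na_option="keep")


def anova_curve_comparison(
    points_a: Sequence[tuple[float, float, int]],
    points_b: Sequence[tuple[float, float, int]],
) -> float:
    """Two-factor fixed-effects ANOVA comparison of two survival curves.

    Fits SF ~ cell_line + dose (both categorical, no interaction) on the
    combined replicate-level points and returns the p value for the
    cell-line main effect, using the classical sums-of-squares
    decomposition. Both datasets must share the same dose grid and carry
    >=2 replicate observations per dose.
    """
    def to_frame(points, label):
        df = pd.DataFrame(points, columns=["dose", "sf", "replicate"])
        df["line"] = label
        return df

    da, db = to_frame(points_a, "A"), to_frame(points_b, "B")
    doses_a, doses_b = set(da["dose"]), set(db["dose"])
    if doses_a != doses_b:
        raise ValueError(
            f"dose grids differ: {sorted(doses_a)} vs {sorted(doses_b)}"
        )
    for name, df in (("A", da), ("B", db)):
        counts = df.groupby("dose").size()
        if (counts < 2).any():
            raise ValueError(
                f"dataset {name}: need >=2 replicate observations per dose"
            )
    data = pd.concat([da, db], ignore_index=True)
    model = ols("sf ~ C(line) + C(dose)", data=data).fit()
    table = anova_lm(model, typ=2)
    p = float(table.loc["C(line)", "PR(>F)"])
    if np.isnan(p):  # zero residual variance with zero effect SS
        f = float(table.loc["C(line)", "F"])
        p = 1.0 if (np.isnan(f) or f == 0.0) else 0.0
    return p


@dataclass(frozen=True)
class FociExperiment:
    """Per-cell nuclear focus counts for (condition x replicate) wells.

    ``conditions`` maps a condition name (cell line x treatment) to a
    list of replicates, each a list of per-cell focus counts. A cell is
    positive when its count strictly exceeds ``threshold`` foci.
    """

    conditions: Mapping[str, Sequence[Sequence[int]]]
    threshold: int = 5

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        conds = {k: [list(rep) for rep in v] for k, v in self.conditions.items()}
        for name, reps in conds.items():
            if not reps:
                raise ValueError(f"condition {name!r}: no replicates")
            for rep in reps:
                if not rep:
                    raise ValueError(f"condition {name!r}: empty replicate")
                if any(c < 0 for c in rep):
                    raise ValueError(f"condition {name!r}: negative focus count")
        object.__setattr__(self, "conditions", conds)

    def positive_fractions(self, condition: str) -> list[float]:
        reps = self.conditions[condition]
        return [
            sum(1 for c in rep if c > self.threshold) / len(rep) for rep in reps
        ]


def foci_positive_fraction(
    exp: FociExperiment,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> tuple[dict[str, list[float]], tuple[float, float]]:
    """Per-replicate positive-cell fractions plus a Student t comparison.

    A cell is scored positive when it has strictly more than
    ``exp.threshold`` nuclear foci. The two-sided equal-variance t test
    compares the per-replicate fractions of two conditions (defaulting
    to the experiment's two conditions); each needs >=2 replicates.
    """
    fractions = {name: exp.positive_fractions(name) for name in exp.conditions}
    if condition_a is None or condition_b is None:
        names = list(exp.conditions)
        if len(names) != 2:
            raise ValueError(
                "specify condition_a/condition_b when the experiment has "
                f"{len(names)} conditions"
            )
        condition_a, condition_b = names
    fa, fb = fractions[condition_a], fractions[condition_b]
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need >=2 replicates per condition for the t test")
    if np.allclose(fa, np.mean(fa + fb)) and np.allclose(fb, np.mean(fa + fb)):
        t, p = 0.0, 1.0  # identical, zero-variance fractions
    else:
        res = stats.ttest_ind(fa, fb, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return fractions, (t, p)
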