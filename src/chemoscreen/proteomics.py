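"""Differential protein abundance between two cell lines from log2 LFQ values.

A protein is called differentially expressed when a two-sided
heteroscedastic (Welch) t-test gives p < 0.05 AND the absolute
difference in mean log2(LFQ) exceeds 3 — both thresholds strict. Missing
LFQ values are excluded per protein, with no imputation; proteins with
fewer than two observed values in either group are skipped with a
reason. Benjamini-Hochberg q-values are included as an extra
convenience column; the significance filter itself uses raw p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LFQMatrix",
    "DifferentialResult",
    "welch_t",
    "differential_proteins",
    "results_frame",
    "read_lfq",
    "write_lfq",
]


@dataclass(frozen=True)
class LFQMatrix:
    """Protein x sample matrix of log2 label-free quantification values."""

    values: pd.DataFrame  # index: protein ids; columns: sample ids
    groups: Mapping[str, str]  # sample id -> "A" | "B"

    def __post_init__(self) -> None:
        groups = {str(k): str(v) for k, v in self.groups.items()}
        levels = set(groups.values())
        if not levels <= {"A", "B"}:
            raise ValueError(f"group labels must be 'A'/'B', got {sorted(levels)}")
        missing = [s for s in self.values.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "values", self.values.astype(float))

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class DifferentialResult:
    protein_id: str
    delta: float  # mean log2(LFQ) difference, B - A
    p_value: float
    significant: bool
    rank_up: int | None
    rank_down: int | None
    skipped_reason: str | None = None


def welch_t(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance t with Welch-Satterthwaite df; two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t needs >=2 non-missing values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups zero-variance with equal means
        p = 1.0
    return float(np.nan_to_num(res.statistic)), p


def differential_proteins(
    m: LFQMatrix, p_max: float = 0.05, delta_min: float = 3.0
) -> list[DifferentialResult]:
    """Per-protein Welch test + effect-size filter, with |delta| ranking.

    delta = mean(group B) - mean(group A) on the log2 scale. Significant
    iff p < p_max (strict) and |delta| > delta_min (strict). Significant
    proteins are ranked by |delta| descending separately within the
    over-expressed (delta > 0) and under-expressed (delta < 0) sets.
    """
    cols_a = m.samples_in("A")
    cols_b = m.samples_in("B")
    results: list[dict] = []
    for pid, row in m.values.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            results.append(
                dict(protein_id=str(pid), delta=np.nan, p_value=np.nan,
                     significant=False,
                     skipped_reason=f"<2 values in a group (nA={a.size}, nB={b.size})")
            )
            continue
        t, p = welch_t(a, b)
        delta = float(b.mean() - a.mean())
        results.append(
            dict(protein_id=str(pid), delta=delta, p_value=p,
                 significant=(p < p_max) and (abs(delta) > delta_min),
                 skipped_reason=None)
        )
    up = sorted(
        (r for r in results if r["significant"] and r["delta"] > 0),
        key=lambda r: -abs(r["delta"]),
    )
    down = sorted(
        (r for r in results if r["significant"] and r["delta"] < 0),
        key=lambda r: -abs(r["delta"]),
    )
    rank_up = {r["protein_id"]: i + 1 for i, r in enumerate(up)}
    rank_down = {r["protein_id"]: i + 1 for i, r in enumerate(down)}
    return [
        DifferentialResult(
            protein_id=r["protein_id"],
            delta=r["delta"],
            p_value=r["p_value"],
            significant=r["significant"],
            rank_up=rank_up.get(r["protein_id"]),
            rank_down=rank_down.get(r["protein_id"]),
            skipped_reason=r["skipped_reason"],
        )
        for r in results
    ]


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabulate differential results, adding Benjamini-Hochberg q-values.

    The q-value column is informational only; the significance flag is
    based on raw p values and the effect-size filter.
    """
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "delta": [r.delta for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "rank_up": [r.rank_up for r in results],
            "rank_down": [r.rank_down for r in results],
            "skipped_reason": [r.skipped_reason or "" for r in results],
        }
    ).set_index("protein_id")
    tested = df["p_value"].notna()
    q = pd.Series(np.nan, index=df.index)
    if tested.any():
        q.loc[tested] = multipletests(df.loc[tested, "p_value"], method="fdr_bh")[1]
    df["q_value_bh"] = q
    return df


def read_lfq(lfq_path: str | Path, groups_path: str | Path) -> LFQMatrix:
    """Read an LFQ matrix (first column protein_id) and a sample->group map."""
    values = pd.read_csv(lfq_path)
    if "protein_id" not in values.columns:
        raise ValueError("LFQ file: missing required column 'protein_id'")
    values = values.set_index("protein_id")
    gdf = pd.read_csv(groups_path)
    for col in ("sample", "group"):
        if col not in gdf.columns:
            raise ValueError(f"groups file: missing required column {col!r}")
    groups = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
    return LFQMatrix(values=values, groups=groups)


def write_lfq(m: LFQMatrix, lfq_path: str | Path, groups_path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "protein_id"
    out.to_csv(lfq_path)
    pd.DataFrame(
        {"sample": list(m.values.columns),
         "group": [m.groups[s] for s in m.values.columns]}
    ).to_csv(groups_path, index=False)
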