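"""Surviving-fraction normalisation and screen quality control.

Luminescence from each well is normalised to the median of the same
plate's DMSO (vehicle-only) control wells, giving a surviving fraction
(SF). Two gates decide whether a cell line's screens enter the final
dataset:

* reproducibility — Pearson correlation between replicate SF vectors
  must exceed ``r_min`` (default 0.7, strict);
* dynamic range — the median per-plate Z' factor must exceed
  ``zprime_min`` (default 0.3, strict), with Z' computed from DMSO
  (negative) and maximum-kill (positive) control wells as
  ``1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|``.

SF values above 1 (wells brighter than the DMSO median) are retained;
clipping happens only inside downstream AUC integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ScreenDataset

__all__ = [
    "SurvivingFractionTable",
    "QCMetrics",
    "QCGateResult",
    "compute_surviving_fractions",
    "zprime_factor",
    "replicate_pearson",
    "compute_qc_metrics",
    "apply_qc_gate",
]


@dataclass(frozen=True)
class SurvivingFractionTable:
    """Per-replicate surviving fractions keyed by (compound_id, conc_nM)."""

    cell_line_id: str
    replicates: tuple[Mapping[tuple[str, float], float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "replicates", tuple(dict(r) for r in self.replicates)
        )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def keys(self) -> set[tuple[str, float]]:
        out: set[tuple[str, float]] = set()
        for rep in self.replicates:
            out |= set(rep)
        return out


@dataclass(frozen=True)
class QCGateResult:
    passed: bool
    failed_criteria: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class QCMetrics:
    cell_line_id: str
    pairwise_pearson: tuple[float, ...]
    zprime_per_plate: tuple[float, ...]
    median_zprime: float = field(init=False)

    def __post_init__(self) -> None:
        for r in self.pairwise_pearson:
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError(f"Pearson r {r} outside [-1, 1]")
        med = float(np.median(self.zprime_per_plate)) if self.zprime_per_plate else np.nan
        object.__setattr__(self, "median_zprime", med)


def compute_surviving_fractions(dataset: ScreenDataset) -> SurvivingFractionTable:
    """Normalise each compound well to its plate's DMSO median.

    Normalisation is strictly per plate: SF = luminescence / median of
    that plate's DMSO wells. Raises if a plate has no measured DMSO well
    or a zero DMSO median.
    """
    replicates = []
    for rep in dataset.replicates:
        lum = {(m.plate_id, m.well): m.luminescence for m in rep.measurements}
        dmso_median: dict[str, float] = {}
        for pid, layout in rep.layouts.items():
            vals = [
                lum[(pid, coord)]
                for coord in layout.wells_with_role("dmso")
                if (pid, coord) in lum
            ]
            if not vals:
                raise ValueError(
                    f"{dataset.cell_line_id} replicate {rep.index}: plate {pid} "
                    f"has no measured DMSO control wells"
                )
            med = float(np.median(vals))
            if med <= 0:
                raise ValueError(
                    f"{dataset.cell_line_id} replicate {rep.index}: plate {pid} "
                    f"DMSO median is {med}; cannot normalise"
                )
            dmso_median[pid] = med
        sf: dict[tuple[str, float], float] = {}
        for (pid, coord), value in lum.items():
            w = rep.layouts[pid].wells.get(coord)
            if w is None or w.role != "compound":
                continue
            sf[(w.compound_id, float(w.conc_nM))] = value / dmso_median[pid]
        replicates.append(sf)
    return SurvivingFractionTable(dataset.cell_line_id, tuple(replicates))


def zprime_factor(neg_lum: Sequence[float], pos_lum: Sequence[float]) -> float:
    """Screening-window coefficient Z' of one plate's control wells.

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|, with sample
    (ddof=1) standard deviations. Z' <= 1 always; 1 only when both
    control groups are noiseless.
    """
    neg = np.asarray(neg_lum, dtype=float)
    pos = np.asarray(pos_lum, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("Z' needs at least 2 wells in each control group")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        raise ValueError("Z' undefined: control means coincide")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window)


def replicate_pearson(sf: SurvivingFractionTable) -> list[float]:
    """Pearson r for every unordered replicate pair over shared points.

    Missing (compound, dose) entries are excluded pairwise; each pair
    must share at least 3 points with nonzero variance on both sides.
    """
    if sf.n_replicates < 2:
        raise ValueError("need at least 2 replicates for correlation")
    out = []
    for i, j in combinations(range(sf.n_replicates), 2):
        shared = sorted(set(sf.replicates[i]) & set(sf.replicates[j]))
        if len(shared) < 3:
            raise ValueError(
                f"replicates {i} and {j} share only {len(shared)} points (<3)"
            )
        a = np.array([sf.replicates[i][k] for k in shared])
        b = np.array([sf.replicates[j][k] for k in shared])
        if a.std() == 0 or b.std() == 0:
            raise ValueError(
                f"replicates {i} and {j}: zero variance, Pearson r undefined"
            )
        out.append(float(stats.pearsonr(a, b).statistic))
    return out


def compute_qc_metrics(dataset: ScreenDataset) -> QCMetrics:
    """Replicate correlations plus one Z' per (replicate, plate)."""
    sf = compute_surviving_fractions(dataset)
    pearson = replicate_pearson(sf)
    zprimes = []
    for rep in dataset.replicates:
        lum = {(m.plate_id, m.well): m.luminescence for m in rep.measurements}
        for pid, layout in rep.layouts.items():
            neg = [lum[(pid, c)] for c in layout.wells_with_role("dmso") if (pid, c) in lum]
            pos = [lum[(pid, c)] for c in layout.wells_with_role("positive") if (pid, c) in lum]
            if len(pos) >= 2 and len(neg) >= 2:
                zprimes.append(zprime_factor(neg, pos))
    return QCMetrics(dataset.cell_line_id, tuple(pearson), tuple(zprimes))


def apply_qc_gate(
    metrics: QCMetrics, r_min: float = 0.7, zprime_min: float = 0.3
) -> QCGateResult:
    """Inclusion gate: median replicate r > r_min AND median Z' > zprime_min.

    Both inequalities are strict; a median Z' of exactly ``zprime_min``
    fails. Returns which criterion (``"pearson"``, ``"zprime"``) failed.
    """
    if not metrics.pairwise_pearson or not metrics.zprime_per_plate:
        raise ValueError("QC metrics are empty; gate undefined")
    failed = []
    if not float(np.median(metrics.pairwise_pearson)) > r_min:
        failed.append("pearson")
    if not metrics.median_zprime > zprime_min:
        failed.append("zprime")
    return QCGateResult(passed=not failed, failed_criteria=tuple(failed))
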