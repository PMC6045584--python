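"""Three-parameter logistic dose-response fitting and activity-area scoring.

The survival model is the three-parameter log-logistic curve with its
lower asymptote fixed at zero::

    SF(c) = d / (1 + (c / e)^b)

where ``b`` is the (Hill) slope, ``d`` the upper asymptote in surviving-
fraction units and ``e`` the ED50 in nM. Replicate surviving fractions
are pooled (no pre-averaging) and fitted by bounded least squares with a
multi-start strategy.

Two area-under-the-curve summaries are integrated over the natural-log
dose axis and normalised by the log-range, so both live in [0, 1]
(1 = no effect, 0 = complete kill):

* unscaled AUC — mean of clip(SF, 0, 1) over log-dose; the complement
  of activity area with reference activity 0;
* scaled AUC — discounts activity already present at the lowest tested
  dose: with activity a(c) = clip(1 - SF(c), 0, 1) and
  A_ref = max(0, a(c_min)),
  ``AUC_s = 1 - mean over log-dose of max(0, a(c) - A_ref)``.

Unscaled AUC matrices are standardised per drug into robust Z scores,
``(AUC - column median) / (1.4826 * MAD)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .qc import SurvivingFractionTable

__all__ = [
    "ThreePLFit",
    "SensitivityScores",
    "three_pl",
    "pool_replicates",
    "fit_three_pl",
    "auc_unscaled",
    "auc_scaled",
    "robust_z_scores",
    "sensitivity_scores",
]

MAD_SCALE = 1.4826  # normal-consistency constant

B_BOUNDS = (0.1, 10.0)
D_BOUNDS = (0.0, 1.5)


def three_pl(c, b: float, d: float, e: float):
    """Evaluate SF(c) = d / (1 + (c/e)^b) elementwise."""
    c = np.asarray(c, dtype=float)
    return d / (1.0 + (c / e) ** b)


@dataclass(frozen=True)
class ThreePLFit:
    """A fitted three-parameter logistic survival curve."""

    compound_id: str
    cell_line_id: str
    b: float
    d: float
    e: float
    converged: bool
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.converged:
            if not self.e > 0:
                raise ValueError("ED50 must be positive")
            if self.d < 0:
                raise ValueError("upper asymptote must be >= 0")

    def predict(self, c):
        return three_pl(c, self.b, self.d, self.e)


@dataclass(frozen=True)
class SensitivityScores:
    compound_id: str
    cell_line_id: str
    auc_unscaled: float
    auc_scaled: float
    a_low: float
    a_ref: float
    z_unscaled: float = np.nan


def pool_replicates(
    sf: SurvivingFractionTable, compound_id: str
) -> list[tuple[float, float]]:
    """Union of all replicate (dose, SF) observations for one compound.

    No averaging: every replicate observation becomes one fit point.
    """
    points = [
        (conc, value)
        for rep in sf.replicates
        for (cid, conc), value in rep.items()
        if cid == compound_id
    ]
    if not points:
        raise KeyError(
            f"compound {compound_id!r} absent from all replicates of "
            f"{sf.cell_line_id}"
        )
    points.sort()
    return points


def fit_three_pl(
    points: list[tuple[float, float]],
    compound_id: str = "",
    cell_line_id: str = "",
) -> ThreePLFit:
    """Bounded least-squares 3PL fit of pooled (conc_nM, SF) points.

    Bounds: b in [0.1, 10], d in [0, 1.5], e in [c_min/100, c_max*100].
    Multi-start initialisation: e at each distinct tested dose crossed
    with b in {0.5, 1, 2}; d starts at the maximum observed SF clipped
    to [0.5, 1.5]. The lowest-RSS solution wins, ties broken by smaller
    slope. ``converged`` is False when every start fails.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (dose, SF) points")
    conc, sf = pts[:, 0], pts[:, 1]
    if np.any(conc <= 0):
        raise ValueError("doses must be positive (log-dose model)")
    doses = np.unique(conc)
    if doses.size < 3:
        raise ValueError(f"need >=3 distinct doses, got {doses.size}")

    e_lo, e_hi = doses.min() / 100.0, doses.max() * 100.0
    lower = np.array([B_BOUNDS[0], D_BOUNDS[0], e_lo])
    upper = np.array([B_BOUNDS[1], D_BOUNDS[1], e_hi])
    d0 = float(np.clip(sf.max(), 0.5, 1.5))

    def residuals(theta):
        return three_pl(conc, *theta) - sf

    best = None
    for e0 in doses:
        for b0 in (0.5, 1.0, 2.0):
            x0 = np.clip([b0, d0, e0], lower, upper)
            try:
                res = optimize.least_squares(
                    residuals, x0, bounds=(lower, upper),
                    xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - scipy internal failure
                continue
            # status 0 (max evaluations) still yields a usable local
            # optimum for degenerate data (e.g. complete kill at every
            # dose, where d and e trade off); only hard failures drop out
            if res.status < 0 or not np.isfinite(res.cost):
                continue
            rss = float(2.0 * res.cost)
            cand = (rss, float(res.x[0]), res.x)
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None:
        return ThreePLFit(
            compound_id, cell_line_id,
            b=np.nan, d=np.nan, e=np.nan,
            converged=False, rss=np.nan, n_points=int(pts.shape[0]),
        )
    rss, _, x = best
    return ThreePLFit(
        compound_id, cell_line_id,
        b=float(x[0]), d=float(x[1]), e=float(x[2]),
        converged=True, rss=rss, n_points=int(pts.shape[0]),
    )


def _check_range(c_min: float, c_max: float) -> None:
    if not (c_min > 0 and c_max > c_min):
        raise ValueError("require 0 < c_min < c_max")


def auc_unscaled(fit: ThreePLFit, c_min: float, c_max: float) -> float:
    """Normalised log-dose integral of clip(SF, 0, 1) over [c_min, c_max].

    Returns NaN (a flagged missing score, not an exception) for a
    non-converged fit. Absolute quadrature tolerance 1e-6.
    """
    _check_range(c_min, c_max)
    if not fit.converged:
        return np.nan
    span = np.log(c_max) - np.log(c_min)

    def integrand(u):
        return np.clip(three_pl(np.exp(u), fit.b, fit.d, fit.e), 0.0, 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, np.log(c_min), np.log(c_max), epsabs=1e-6, limit=200
        )
    return float(val / span)


def auc_scaled(fit: ThreePLFit, c_min: float, c_max: float) -> float:
    """Scaled AUC: dose-dependent activity beyond the lowest-dose baseline.

    With a(c) = clip(1 - SF(c), 0, 1) and A_ref = max(0, a(c_min)):
    AUC_s = 1 - (1/L) * integral of max(0, a(c) - A_ref) d(ln c).
    Reduces to the unscaled AUC when a(c_min) = 0 and equals 1 for any
    dose-flat activity profile.
    """
    _check_range(c_min, c_max)
    if not fit.converged:
        return np.nan
    span = np.log(c_max) - np.log(c_min)

    def activity(u):
        return np.clip(1.0 - three_pl(np.exp(u), fit.b, fit.d, fit.e), 0.0, 1.0)

    a_ref = max(0.0, float(activity(np.log(c_min))))

    def integrand(u):
        return np.maximum(0.0, activity(u) - a_ref)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, np.log(c_min), np.log(c_max), epsabs=1e-6, limit=200
        )
    return float(1.0 - val / span)


def sensitivity_scores(
    fit: ThreePLFit, c_min: float, c_max: float
) -> SensitivityScores:
    """Bundle unscaled/scaled AUC with the lowest-dose activity terms."""
    if fit.converged:
        a_low = float(np.clip(1.0 - fit.predict(c_min), 0.0, 1.0))
    else:
        a_low = np.nan
    return SensitivityScores(
        compound_id=fit.compound_id,
        cell_line_id=fit.cell_line_id,
        auc_unscaled=auc_unscaled(fit, c_min, c_max),
        auc_scaled=auc_scaled(fit, c_min, c_max),
        a_low=a_low,
        a_ref=max(0.0, a_low) if np.isfinite(a_low) else np.nan,
    )


def robust_z_scores(auc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each drug column against the cell-line panel.

    Z_i = (AUC_i - median(column)) / (1.4826 * MAD(column)), MAD being the
    median absolute deviation from the column median. Missing values
    propagate; a zero-MAD column becomes all-missing with a warning.
    """
    out = pd.DataFrame(
        np.nan, index=auc_matrix.index, columns=auc_matrix.columns, dtype=float
    )
    for col in auc_matrix.columns:
        x = auc_matrix[col].astype(float)
        obs = x.dropna()
        if len(obs) < 3:
            raise ValueError(f"column {col!r}: need >=3 non-missing values")
        med = float(obs.median())
        mad = float((obs - med).abs().median())
        if mad == 0:
            warnings.warn(
                f"column {col!r}: zero MAD, robust Z undefined; emitting missing",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[col] = (x - med) / (MAD_SCALE * mad)
    return out
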