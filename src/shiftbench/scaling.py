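"""The linear scaling model converting isotropic shieldings to chemical shifts.

A computed isotropic shielding sigma (ppm) maps onto a chemical shift delta
(ppm) through an empirically fitted line

    delta = (b - sigma) / (-m)

where the slope ``m`` (dimensionless, close to -1) and intercept ``b`` (ppm)
are obtained by ordinary least squares of sigma on delta_exp over a training
set: sigma = m * delta + b.  The regression cancels the bulk of the systematic
error of a given model chemistry, so each (functional, basis, solvent, gauge,
geometry) combination carries its own factor pair per nucleus.

Recommended factor pairs for the two reference model chemistries are shipped
as named constants (``RECOMMENDED_FACTORS``): "method1" trades a little
accuracy for speed, "method2" is the high-accuracy protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .dataset import Nucleus

__all__ = [
    "ScalingFactors",
    "ShiftPrediction",
    "RECOMMENDED_FACTORS",
    "LEGACY_H1_FACTORS",
    "LEGACY_C13_FACTORS",
    "DegenerateFitError",
    "fit_scaling",
    "predict_shift",
    "predict_shifts",
    "compare_scalings",
]


class DegenerateFitError(ValueError):
    """All experimental shifts identical, or fewer than two pairs."""


@dataclass(frozen=True)
class ScalingFactors:
    """Slope/intercept of the scaling line with fit diagnostics.

    ``fit_rmsd`` is the RMSD (ppm) of back-predicted shifts over the training
    pairs; it is NaN for factor pairs not produced by fitting.
    """

    nucleus: Nucleus
    slope_m: float
    intercept_b: float
    n_points: int = 0
    r_squared: float = float("nan")
    fit_rmsd: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope_m == 0:
            raise ValueError("slope_m must be nonzero")
        if not math.isnan(self.r_squared) and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def shift_from_shielding(self, sigma: float) -> float:
        """Apply the scaling line: delta = (b - sigma) / (-m)."""
        return (self.intercept_b - sigma) / (-self.slope_m)

    def shielding_from_shift(self, delta: float) -> float:
        """Invert the scaling line: sigma = m * delta + b."""
        return self.slope_m * delta + self.intercept_b


@dataclass(frozen=True)
class ShiftPrediction:
    compound_id: str
    site_label: str
    nucleus: Nucleus
    sigma_used: float  # ensemble- and equivalence-averaged shielding, ppm
    delta_pred: float  # ppm
    residual: Optional[float] = None  # delta_pred - delta_exp, ppm


# Published factor pairs for the two recommended protocols.
# method1 = speed+efficiency (B3LYP/6-31G(d) geometries, WP04/jul-cc-pVDZ for
# 1H, wB97X-D/def2-SVP for 13C); method2 = high accuracy
# (PCM-B3LYP-D3/6-311G(d,p) geometries, WP04/6-311++G(2d,p) for 1H).
RECOMMENDED_FACTORS: dict[str, dict[Nucleus, ScalingFactors]] = {
    "method1": {
        Nucleus.H1: ScalingFactors(Nucleus.H1, -1.0309, 31.8883),
        Nucleus.C13: ScalingFactors(Nucleus.C13, -1.0081, 195.6683),
    },
    "method2": {
        Nucleus.H1: ScalingFactors(Nucleus.H1, -1.0311, 32.2654),
        Nucleus.C13: ScalingFactors(Nucleus.C13, -1.0065, 196.0386),
    },
}

# B3LYP/cc-pVTZ//B3LYP/6-31G(d) factors fitted against the older literature
# shift compilation vs the re-measured data; used for cross-dataset comparison.
LEGACY_H1_FACTORS = (
    ScalingFactors(Nucleus.H1, -1.0429, 31.6499),  # older literature data
    ScalingFactors(Nucleus.H1, -1.0450, 31.6889),  # re-measured data
)
LEGACY_C13_FACTORS = (
    ScalingFactors(Nucleus.C13, -1.0372, 181.5955),
    ScalingFactors(Nucleus.C13, -1.0364, 181.5727),
)


def fit_scaling(
    pairs: Iterable[tuple[float, float]], nucleus: Nucleus
) -> ScalingFactors:
    """Fit the scaling line by OLS of sigma on delta_exp.

    Parameters
    ----------
    pairs
        (delta_exp ppm, sigma ppm) tuples, pooled over all compounds.
    nucleus
        Nucleus tag recorded on the result.

    Returns slope, intercept, n, r-squared, and the RMSD of back-predicted
    shifts over the training pairs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise DegenerateFitError("need at least two (delta_exp, sigma) pairs")
    delta, sigma = arr[:, 0], arr[:, 1]
    if np.ptp(delta) == 0:
        raise DegenerateFitError("all delta_exp values identical; slope undefined")
    res = stats.linregress(delta, sigma)
    m, b = float(res.slope), float(res.intercept)
    if m == 0:
        raise DegenerateFitError("fitted slope is zero; scaling line is not invertible")
    back = (b - sigma) / (-m)
    rmsd = float(np.sqrt(np.mean((back - delta) ** 2)))
    return ScalingFactors(
        nucleus=nucleus,
        slope_m=m,
        intercept_b=b,
        n_points=len(arr),
        r_squared=float(res.rvalue**2),
        fit_rmsd=rmsd,
    )


def predict_shift(sigma: float, factors: ScalingFactors) -> float:
    """Scalar form of the scaling map delta = (b - sigma)/(-m)."""
    return factors.shift_from_shielding(sigma)


def predict_shifts(
    sigmas: Sequence[tuple[str, str, float]] | dict,
    factors: ScalingFactors,
    delta_exp: Optional[dict[tuple[str, str], float]] = None,
) -> list[ShiftPrediction]:
    """Convert per-site shieldings into shift predictions.

    Parameters
    ----------
    sigmas
        Either a mapping {(compound_id, site_label): sigma} or a sequence of
        (compound_id, site_label, sigma) triples.
    factors
        Scaling factors for the matching nucleus.
    delta_exp
        Optional experimental shifts keyed like ``sigmas``; when present the
        residual delta_pred - delta_exp is attached.
    """
    if isinstance(sigmas, dict):
        triples = [(cid, lbl, s) for (cid, lbl), s in sigmas.items()]
    else:
        triples = list(sigmas)
    out = []
    for cid, lbl, sigma in triples:
        pred = factors.shift_from_shielding(sigma)
        resid = None
        if delta_exp is not None and (cid, lbl) in delta_exp:
            resid = pred - delta_exp[(cid, lbl)]
        out.append(
            ShiftPrediction(
                compound_id=cid,
                site_label=lbl,
                nucleus=factors.nucleus,
                sigma_used=sigma,
                delta_pred=pred,
                residual=resid,
            )
        )
    return out


def compare_scalings(
    f1: ScalingFactors, f2: ScalingFactors, delta_range: tuple[float, float]
) -> tuple[float, float]:
    """Maximum absolute prediction difference between two factor pairs.

    For a shift delta in the range, the first line gives the shielding
    sigma = m1*delta + b1 and the second line re-predicts
    delta' = (b2 - sigma)/(-m2).  The difference delta' - delta is affine in
    delta, so its maximum absolute value over a closed interval is attained at
    an endpoint; it is evaluated in closed form.

    Returns (max |difference| in ppm, the endpoint where it is attained).
    """
    if f1.nucleus != f2.nucleus:
        raise ValueError("factor pairs are for different nuclei")
    lo, hi = delta_range
    if not lo < hi:
        raise ValueError("delta_range must satisfy lo < hi")
    if (f1.slope_m, f1.intercept_b) == (f2.slope_m, f2.intercept_b):
        return 0.0, lo  # identical lines: the map is the identity

    def diff(delta: float) -> float:
        sigma = f1.shielding_from_shift(delta)
        return f2.shift_from_shielding(sigma) - delta

    d_lo, d_hi = diff(lo), diff(hi)
    if abs(d_lo) >= abs(d_hi):
        return abs(d_lo), lo
    return abs(d_hi), hi
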