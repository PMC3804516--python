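"""Growth-rate and yield estimation from fermentation time series.

The net specific growth rate mu_net (1/h) is the least-squares slope of
ln(OD600) versus time from the end of the lag phase to the time of maximum
cell density. Lag end is detected as the first time OD exceeds
(1 + epsilon) times the initial OD (epsilon default 0.2). End-product
yields (g product per g substrate utilized) are slopes of product
concentration against substrate consumed over the exponential window.

Pairs of conditions/strains are compared by ANCOVA: a pooled regression
y ~ x + z with z a 0/1 treatment indicator (main-effect form); the
interaction form y ~ x + z + x:z, which compares slopes directly, is
offered as an option. Significance is judged at alpha = 0.05 on the
treatment (or interaction) term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import GrowthCurve, ValidationError


@dataclass(frozen=True)
class GrowthFit:
    strain: str
    condition: str
    lag_end: float
    t_max_od: float
    mu_net: float
    r_squared: float
    n_points: int


class FitError(ValueError):
    """Raised when a regression cannot be formed from the data."""


def detect_lag_end(curve: GrowthCurve, epsilon: float = 0.2) -> float:
    """First sampling time from which OD stays above (1 + epsilon) x OD(0).

    The baseline OD(0) is estimated as the median of the first three
    readings, and the crossing must be sustained (every reading from lag
    end to the OD peak stays above threshold); both guards protect the
    rule from single noisy readings and reduce to the plain
    first-crossing-of-the-first-reading rule on noise-free monotone
    curves.
    """
    od0 = float(np.median(curve.od[:3]))
    above = curve.od > (1.0 + epsilon) * od0
    if not above.any():
        raise FitError("OD never rises above the lag threshold; no growth detected")
    peak = int(np.argmax(curve.od))
    # first index from which every reading up to the OD peak is above threshold
    sustained = len(curve.od)
    for i in range(peak, -1, -1):
        if above[i]:
            sustained = i
        else:
            break
    if sustained == len(curve.od):
        raise FitError("no sustained rise above the lag threshold")
    return float(curve.times[sustained])


def fit_growth_rate(curve: GrowthCurve, epsilon: float = 0.2) -> GrowthFit:
    """Fit mu_net over [lag end, time of maximum OD].

    Non-positive OD readings (blank-referenced negatives) are excluded from
    the log fit; at least 3 usable points are required.
    """
    lag_end = detect_lag_end(curve, epsilon)
    t_max = float(curve.times[int(np.argmax(curve.od))])
    if lag_end >= t_max:
        raise FitError(f"lag end {lag_end} h not before maximum-OD time {t_max} h")
    mask = (curve.times >= lag_end) & (curve.times <= t_max) & (curve.od > 0)
    if mask.sum() < 3:
        raise FitError(f"only {int(mask.sum())} usable points in the exponential window")
    res = stats.linregress(curve.times[mask], np.log(curve.od[mask]))
    return GrowthFit(
        strain=curve.strain,
        condition=curve.condition,
        lag_end=lag_end,
        t_max_od=t_max,
        mu_net=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


@dataclass(frozen=True)
class YieldFit:
    product: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_yield(
    product: np.ndarray,
    substrate_utilized: np.ndarray,
    product_name: str = "",
    window: slice | np.ndarray | None = None,
) -> YieldFit:
    """Least-squares slope of product formed vs substrate utilized.

    ``window`` restricts the regression to the exponential-phase samples
    (a slice or boolean mask over the aligned series).
    """
    y = np.asarray(product, dtype=float)
    x = np.asarray(substrate_utilized, dtype=float)
    if window is not None:
        y, x = y[window], x[window]
    if len(x) < 3:
        raise FitError(f"yield regression needs >= 3 points, got {len(x)}")
    res = stats.linregress(x, y)
    return YieldFit(
        product=product_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def substrate_utilized(substrate: np.ndarray) -> np.ndarray:
    """Convert a substrate concentration series to cumulative utilization."""
    s = np.asarray(substrate, dtype=float)
    return s[0] - s


@dataclass(frozen=True)
class AncovaResult:
    comparison: str
    coefficient: float
    p_value: float
    significant: bool
    model_form: str  # main_effect | interaction


def ancova_compare(
    series_a: tuple[np.ndarray, np.ndarray],
    series_b: tuple[np.ndarray, np.ndarray],
    model_form: str = "main_effect",
    comparison: str = "",
    alpha: float = 0.05,
) -> AncovaResult:
    """Pooled-regression comparison of two (x, y) series.

    ``main_effect`` tests the treatment intercept term in y ~ x + z;
    ``interaction`` tests the slope-difference term in y ~ x + z + x:z.
    Note the main-effect form compares offsets, not slopes — it is kept as
    the default because it is the conventional reporting form for these
    fermentation comparisons, with the interaction form available when a
    slope contrast is wanted.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in series_a)
    xb, yb = (np.asarray(v, dtype=float) for v in series_b)
    if len(xa) < 3 or len(xb) < 3:
        raise FitError("both series need >= 3 points")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    z = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    if model_form == "main_effect":
        design = np.column_stack([x, z])
        term = 2  # const, x, z
    elif model_form == "interaction":
        design = np.column_stack([x, z, x * z])
        term = 3  # const, x, z, x:z
    else:
        raise ValidationError(f"unknown model_form {model_form!r}")
    design = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("collinear inputs; ANCOVA design is rank-deficient")
    fit = sm.OLS(y, design).fit()
    coef = float(fit.params[term])
    p = float(fit.pvalues[term])
    return AncovaResult(
        comparison=comparison,
        coefficient=coef,
        p_value=p,
        significant=bool(p < alpha),
        model_form=model_form,
    )
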