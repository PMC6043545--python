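"""Per-stock sensitivity of predicted F/Fmsy to driver perturbations.

For each continuous driver the question is: if the driver moved by
+/-25% (each row's own value scaled by 1.25 or 0.75) with everything
else held constant, by what percent would the predicted F/Fmsy change?
Per row that is 100 * (yhat_perturbed - yhat) / yhat; a stock's
elasticity is the mean over its observed rows, which keeps each row's
gear/species dummy configuration intact.  Because the fitted model is
linear, the +25% and -25% effects are equal in magnitude and opposite
in sign, and a driver with a zero coefficient has exactly zero
elasticity.  Percent changes are ill-behaved when a baseline
prediction sits near zero; such stocks carry a stability flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import CONTINUOUS_COLUMNS, KEY_COLUMNS
from .ridge import RidgeFit
from .stocks import CLIMATE_INDICES

#: the 15 continuous drivers perturbed by default
DEFAULT_FEATURES: tuple[str, ...] = tuple(CONTINUOUS_COLUMNS) + CLIMATE_INDICES

STABILITY_THRESHOLD = 0.05


@dataclass
class ElasticityResult:
    """Mean percent response of one stock to one perturbed driver."""

    stock: str
    feature: str
    direction: str  # "+25%" / "-25%"
    pct_change_f: float
    n_rows: int
    stability_flag: bool


def _direction_label(factor: float) -> str:
    return f"{'+' if factor >= 0 else '-'}{abs(factor) * 100:g}%"


def perturb_predict(
    fit: RidgeFit,
    table: pd.DataFrame,
    feature: str,
    factor: float = 0.25,
) -> list[ElasticityResult]:
    """Elasticity of each stock to scaling one driver by (1 + factor).

    The perturbed prediction is recomputed from the fitted model (not
    short-circuited analytically), so the routine remains valid for any
    predictor-driven model exposing ``predict``.
    """
    if feature not in fit.coefficients:
        raise ValidationError(f"feature {feature!r} is not a predictor of the fit")
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"table missing key columns: {missing}")

    x = table[fit.columns]
    baseline = fit.predict(x)
    perturbed_x = x.copy()
    perturbed_x[feature] = perturbed_x[feature] * (1.0 + factor)
    perturbed = fit.predict(perturbed_x)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (perturbed - baseline) / baseline

    out = []
    label = _direction_label(factor)
    frame = pd.DataFrame({"stock": table["stock"].to_numpy(), "pct": pct, "baseline": baseline})
    for stock, grp in frame.groupby("stock", sort=True):
        unstable = bool((grp["baseline"].abs() < STABILITY_THRESHOLD).any())
        if (grp["baseline"] <= 0).all():
            value = np.nan
            unstable = True
        else:
            value = float(grp["pct"].mean())
        out.append(
            ElasticityResult(
                stock=stock,
                feature=feature,
                direction=label,
                pct_change_f=value,
                n_rows=len(grp),
                stability_flag=unstable,
            )
        )
    return out


def analytic_pct_change(fit: RidgeFit, table: pd.DataFrame, feature: str, factor: float) -> pd.Series:
    """Closed-form per-row percent change for a linear fit.

    delta yhat = beta_feature * factor * x_feature, so the per-row
    percent change is 100 * beta * factor * x / yhat.  Used as the
    independent cross-check of :func:`perturb_predict`.
    """
    beta = fit.coefficients[feature]
    x = table[fit.columns]
    yhat = fit.predict(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * beta * factor * table[feature].to_numpy(dtype=float) / yhat
    return pd.Series(pct, index=table.index)


def elasticity_matrix(
    fit: RidgeFit,
    table: pd.DataFrame,
    features=DEFAULT_FEATURES,
    factor: float = 0.25,
    stock_registry=None,
) -> pd.DataFrame:
    """Full stock x driver x direction elasticity table.

    Returns one row per (stock, feature, direction in {+, -}) with the
    mean percent change in predicted F/Fmsy, row counts, the stability
    flag, and (when a stock registry is supplied or available) the
    stock's species and tRFMO for plotting.
    """
    rows = []
    for feature in features:
        for f in (abs(factor), -abs(factor)):
            for res in perturb_predict(fit, table, feature, f):
                rows.append(
                    {
                        "stock": res.stock,
                        "feature": res.feature,
                        "direction": res.direction,
                        "pct_change": res.pct_change_f,
                        "magnitude": abs(res.pct_change_f),
                        "n_rows": res.n_rows,
                        "stability_flag": res.stability_flag,
                    }
                )
    out = pd.DataFrame(rows)
    if stock_registry is None:
        from .stocks import DEFAULT_STOCKS as stock_registry  # noqa: N813
    known = out["stock"].isin(stock_registry)
    out["species"] = out["stock"].where(known).map(
        lambda s: stock_registry[s].species if isinstance(s, str) else None
    )
    out["trfmo"] = out["stock"].where(known).map(
        lambda s: stock_registry[s].org if isinstance(s, str) else None
    )
    return out
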