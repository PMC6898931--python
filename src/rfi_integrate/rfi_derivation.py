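"""Residual feed intake as the residual of the feed-intake regression.

Daily feed intake is regressed on an intercept, average daily gain,
metabolic mid-weight (mid-test weight raised to a metabolic exponent,
0.73 by default) and test-group indicators.  The per-animal residual is
the RFI phenotype: negative values mark animals eating less than
predicted from their growth and size, i.e. the feed-efficient ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import FeedlotTable


@dataclass
class RFIModelFit:
    """Fitted feed-intake regression and the residuals that define RFI."""

    beta0: float
    beta1: float            # partial regression on ADG (kg feed / kg gain)
    beta2: float            # partial regression on metabolic mid-weight
    group_effects: dict[str, float]   # deviations from the baseline group
    residuals: pd.Series    # RFI, indexed by animal_id (kg/day)
    r2: float
    mmwt_exponent: float


def _name_collinear_columns(X: pd.DataFrame) -> list[str]:
    """Identify columns linearly dependent on the ones before them."""
    bad, kept = [], []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if kept:
            basis = X[kept].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
            if np.linalg.norm(v - basis @ coef) < 1e-8 * max(
                    1.0, np.linalg.norm(v)):
                bad.append(col)
                continue
        elif np.allclose(v, 0):
            bad.append(col)
            continue
        kept.append(col)
    return bad


def fit_rfi(table: FeedlotTable, mmwt_exponent: float = 0.73) -> RFIModelFit:
    """Fit the feed-intake regression and return residuals as RFI.

    Test groups are coded as treatment contrasts against the
    first-observed level; only the residuals are consumed downstream, so
    the contrast choice does not affect any result.  ``mwt`` enters as
    ``mwt ** mmwt_exponent``.
    """
    df = table.data
    if df[["dfi", "adg", "mwt"]].isna().any().any():
        raise ValueError("missing dfi/adg/mwt values")
    groups = df["test_group"].astype(str)
    levels = list(dict.fromkeys(groups))
    counts = groups.value_counts()

    X = pd.DataFrame({"const": 1.0,
                      "adg": df["adg"].astype(float),
                      "mmwt": df["mwt"].astype(float) ** mmwt_exponent})
    for lev in levels[1:]:
        X[f"group[{lev}]"] = (groups == lev).astype(float)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = _name_collinear_columns(X)
        singletons = [lev for lev in levels if counts[lev] < 2]
        hint = (f"; test groups with a single animal: {singletons}"
                if singletons else "")
        raise ValueError(
            f"rank-deficient design; collinear columns: {bad}{hint}")

    res = sm.OLS(df["dfi"].astype(float).to_numpy(), X).fit()
    params = res.params
    group_effects = {levels[0]: 0.0}
    group_effects.update(
        {lev: float(params[f"group[{lev}]"]) for lev in levels[1:]})
    residuals = pd.Series(np.asarray(res.resid),
                          index=df["animal_id"].astype(str), name="rfi")
    return RFIModelFit(
        beta0=float(params["const"]),
        beta1=float(params["adg"]),
        beta2=float(params["mmwt"]),
        group_effects=group_effects,
        residuals=residuals,
        r2=float(res.rsquared),
        mmwt_exponent=float(mmwt_exponent),
    )
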