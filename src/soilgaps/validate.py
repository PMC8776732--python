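"""Paired validation of network sensors against an independent reference.

Capacitance-probe readings are validated against co-located reference
measurements (e.g. Time Domain Reflectometry) taken on the same calendar day
and in the same microsite.  The sensor reading is regressed on the reference
value by ordinary least squares — the reference is treated as the trusted
predictor — and the fit is summarized by the slope with its two-sided 95%
confidence interval (Student t, n-2 degrees of freedom) and the adjusted
coefficient of determination

    adj R2 = 1 - (1 - R2) (n - 1) / (n - 2).

A slope near 1 with a tight interval and high adjusted R2 indicates the
probes track true soil moisture across its range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EligibilityError
from .io import meta_frame


@dataclass(frozen=True)
class ValidationResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    ci_low: float
    ci_high: float
    slope_stderr: float

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "slope_stderr": self.slope_stderr,
        }


def paired_regression(pairs: pd.DataFrame) -> ValidationResult:
    """OLS of ``sensor_vwc`` (response) on ``reference_vwc`` (predictor).

    ``pairs`` needs columns ``sensor_vwc`` and ``reference_vwc`` with at
    least 3 complete rows and a non-constant reference.
    """
    data = pairs[["reference_vwc", "sensor_vwc"]].dropna()
    n = len(data)
    if n < 3:
        raise EligibilityError(f"need at least 3 complete pairs, got {n}")
    x = data["reference_vwc"].to_numpy(dtype=float)
    y = data["sensor_vwc"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise EligibilityError("reference values are all equal; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return ValidationResult(
        n=n,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        slope_stderr=float(model.bse[1]),
    )


def pair_measurements(
    table: pd.DataFrame,
    meta,
    references: pd.DataFrame,
) -> pd.DataFrame:
    """Match reference measurements to sensor readings by day and microsite.

    ``references`` needs columns ``timestamp`` (or ``date``), ``microsite``
    and ``reference_vwc``.  Each reference row is paired with the sensor
    reading closest in time within the same calendar day, averaging the
    microsite's replicates where more than one is observed.  Reference rows
    with no observed sensor value that day are dropped.

    Returns a frame with columns ``date, microsite, sensor_vwc,
    reference_vwc`` ready for :func:`paired_regression`.
    """
    refs = references.copy()
    tcol = "timestamp" if "timestamp" in refs.columns else "date"
    refs[tcol] = pd.to_datetime(refs[tcol])
    mf = meta_frame(meta)
    by_site = {
        site: list(mf.index[mf["microsite"] == site]) for site in mf["microsite"].unique()
    }
    days = table.index.normalize()
    rows = []
    for ref in refs.itertuples():
        t_ref = getattr(ref, tcol)
        sensors = by_site.get(ref.microsite, [])
        if not sensors:
            continue
        same_day = days == t_ref.normalize()
        site_vals = table.loc[same_day, sensors]
        avail = site_vals.notna().any(axis=1)
        if not avail.any():
            continue
        cand = site_vals.loc[avail]
        nearest = (cand.index - t_ref).to_numpy(dtype="timedelta64[ns]")
        pick = cand.index[np.abs(nearest).argmin()]
        rows.append(
            {
                "date": pick,
                "microsite": ref.microsite,
                "sensor_vwc": float(cand.loc[pick].mean()),
                "reference_vwc": float(ref.reference_vwc),
            }
        )
    return pd.DataFrame(rows, columns=["date", "microsite", "sensor_vwc", "reference_vwc"])


def plot_validation(pairs: pd.DataFrame, result: ValidationResult, path) -> None:
    """Scatter of sensor vs reference VWC with the fitted line and 1:1 guide."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs["reference_vwc"], pairs["sensor_vwc"], s=18, alpha=0.7)
    lo = float(min(pairs["reference_vwc"].min(), 0.0))
    hi = float(pairs["reference_vwc"].max()) * 1.05
    xs = np.linspace(lo, hi, 50)
    ax.plot(xs, result.intercept + result.slope * xs, "r-", label="OLS fit")
    ax.plot(xs, xs, "k--", lw=0.8, label="1:1")
    ax.set_xlabel("reference VWC (m$^3$/m$^3$)")
    ax.set_ylabel("sensor VWC (m$^3$/m$^3$)")
    ax.set_title(
        f"slope={result.slope:.3f} [{result.ci_low:.3f}, {result.ci_high:.3f}], "
        f"adj $R^2$={result.adj_r_squared:.3f}, n={result.n}"
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
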