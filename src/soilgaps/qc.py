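"""Quality control: range-based anomaly flagging and missingness accounting.

Capacitance probes occasionally report small negative VWC values (imbalances
in the standard calibration equation, within the sensor's margin of error).
These anomalous readings are set to missing before imputation.  The bounds
are inclusive — a reading of exactly 0.0 is retained — and the upper bound
of 1.0 (the physical ceiling of a volume fraction) is an additional guard;
both are configurable.

The manual plausibility check a field scientist performs — comparing a
suspect probe against a trustworthy neighbour — is available as an advisory
report (:func:`peer_consistency`) that flags sensors whose agreement with
their microsite peers degrades; it never deletes data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import meta_frame, validate_table


@dataclass
class MissingnessReport:
    """Cell counts for one sensor table.

    ``pct_missing`` is stored at full precision; round only for display.
    """

    n_total: int
    n_missing: int
    n_anomalous_set_na: int = 0

    @property
    def pct_missing(self) -> float:
        return 100.0 * self.n_missing / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": int(self.n_total),
            "n_missing": int(self.n_missing),
            "n_anomalous_set_na": int(self.n_anomalous_set_na),
            "pct_missing": self.pct_missing,
        }

    def __str__(self) -> str:  # presentation rounds to 1 d.p.
        return (
            f"{self.n_missing:,} of {self.n_total:,} cells missing "
            f"({self.pct_missing:.1f}%)"
        )


def summarize_missingness(table: pd.DataFrame) -> MissingnessReport:
    """Count grid cells and missing cells; n_total = timestamps x sensors."""
    validate_table(table)
    n_total = int(table.size)
    n_missing = int(table.isna().to_numpy().sum())
    return MissingnessReport(n_total=n_total, n_missing=n_missing)


def flag_anomalies(
    table: pd.DataFrame, lower: float = 0.0, upper: float = 1.0
) -> tuple[pd.DataFrame, MissingnessReport]:
    """Set cells strictly below ``lower`` or above ``upper`` to missing.

    Idempotent; in-range cells pass through unchanged and already-missing
    cells stay missing.  The report counts the conversions performed and the
    resulting missingness.
    """
    if not lower < upper:
        raise ValueError(f"require lower < upper, got {lower} / {upper}")
    validate_table(table)
    vals = table.to_numpy(dtype=float)
    bad = (vals < lower) | (vals > upper)  # NaN compares False: missing untouched
    out = table.mask(pd.DataFrame(bad, index=table.index, columns=table.columns))
    report = summarize_missingness(out)
    report.n_anomalous_set_na = int(bad.sum())
    return out, report


def peer_consistency(
    table: pd.DataFrame,
    meta,
    freq: str = "MS",
    min_overlap: int = 20,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Advisory per-sensor agreement with microsite peers over trailing windows.

    For each sensor and each calendar window (default monthly), computes the
    Pearson correlation between the sensor and the mean of its same-microsite
    peers on their common valid cases.  Windows with fewer than
    ``min_overlap`` common cases get a missing correlation.  Rows with
    ``flagged=True`` (correlation below ``threshold``) deserve human review;
    nothing is modified or deleted.
    """
    validate_table(table)
    mf = meta_frame(meta)
    rows = []
    for sid in table.columns:
        peers = [
            s
            for s in table.columns
            if s != sid and mf.loc[s, "microsite"] == mf.loc[sid, "microsite"]
        ]
        if not peers:
            continue
        peer_mean = table[peers].mean(axis=1)
        for window, chunk in table[sid].groupby(pd.Grouper(freq=freq)):
            ref = peer_mean.loc[chunk.index]
            both = chunk.notna() & ref.notna()
            n = int(both.sum())
            if n >= min_overlap and chunk[both].std() > 0 and ref[both].std() > 0:
                r = float(np.corrcoef(chunk[both], ref[both])[0, 1])
            else:
                r = np.nan
            rows.append(
                {
                    "sensor_id": sid,
                    "window": window,
                    "n_common": n,
                    "r_peer": r,
                    "flagged": bool(r < threshold) if np.isfinite(r) else False,
                }
            )
    return pd.DataFrame(rows)
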