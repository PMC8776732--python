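"""Donor-based gap filling for sensor networks.

For a target sensor *y* with a missing value at time *t*, every other sensor
*x* is scored as a candidate donor with the composite selection score

    S_x = %vc_{x,y} + 100 * R2_{x,y} + (100 if same microsite else 0)

where %vc is the percent of common valid cases (timestamps at which both
sensors hold an observed value, as a percentage of the full grid length, so
longer shared coverage scores higher) and R2 is the squared Pearson
correlation of those common cases.  The same-microsite preference enters only
through the +100 bonus, so a cross-microsite donor can win on overwhelming
overlap and correlation.  The score ranges over [0, 300].

Each gap is filled from the highest-scoring donor that is *observed* at that
timestamp, using an ordinary least-squares model y = a + b*x fitted once per
(donor, target) pair on all their common valid cases.  Predictions are
clipped into [0, 1] (a negative prediction would immediately re-trigger the
range QC).  By default imputed values never serve as donors for later fills —
a single pass over originally observed data, which prevents error cascades;
an iterative mode re-runs passes until no further cell can be filled.

Provenance is tracked in a quality grid aligned with the table: 1 where the
value was observed, the donor model's Pearson correlation coefficient where
it was imputed, missing where no donor could fill it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EligibilityError
from .io import SensorMeta, meta_frame, validate_table


@dataclass(frozen=True)
class PairStats:
    """Selection-score statistics for one ordered (donor, target) pair."""

    target_id: str
    donor_id: str
    n_common: int
    pct_valid_common: float
    r: float
    r_squared: float
    same_microsite: bool
    score: float
    eligible: bool  # False when n_common < 2 or a series is constant on the overlap


@dataclass(frozen=True)
class LinearFit:
    """OLS model ``target = intercept + slope * donor`` on common valid cases."""

    target_id: str
    donor_id: str
    intercept: float
    slope: float
    r: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ImputeConfig:
    """Tunable parameters of the gap-filling pass.

    min_overlap
        Minimum number of common valid cases for a donor model; stabilizes
        the OLS slope on sub-daily records.
    iterative
        Re-run passes letting previously imputed cells act as donors, until
        no further cell can be filled.  Off by default.
    clip
        Clip predictions into [0, 1].
    """

    min_overlap: int = 100
    iterative: bool = False
    clip: bool = True


@dataclass
class ImputationReport:
    """Aggregate accounting plus the per-gap donor decision log."""

    n_missing_before: int
    n_filled: int
    n_missing_after: int
    gap_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n_missing_before": int(self.n_missing_before),
            "n_filled": int(self.n_filled),
            "n_missing_after": int(self.n_missing_after),
        }


def pair_statistics(
    table: pd.DataFrame,
    meta: list[SensorMeta],
    donor_id: str,
    target_id: str,
) -> PairStats:
    """Compute the selection-score statistics for one ordered donor/target pair.

    ``n_common`` counts timestamps where both sensors hold an observed value;
    ``pct_valid_common`` is that count as a percentage of the grid length.
    When fewer than two common cases exist, or either series is constant on
    the overlap, the correlation is undefined: r and R2 are reported as 0 and
    the pair is marked ineligible.
    """
    if donor_id == target_id:
        raise EligibilityError(f"donor and target are the same sensor ({donor_id!r})")
    validate_table(table)
    mf = meta_frame(meta)
    x = table[donor_id].to_numpy(dtype=float)
    y = table[target_id].to_numpy(dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    n_common = int(both.sum())
    pct = 100.0 * n_common / len(table.index)
    xx, yy = x[both], y[both]
    eligible = n_common >= 2 and np.ptp(xx) > 0 and np.ptp(yy) > 0
    if eligible:
        r = float(np.corrcoef(xx, yy)[0, 1])
        r2 = r * r
    else:
        r, r2 = 0.0, 0.0
    same = bool(mf.loc[donor_id, "microsite"] == mf.loc[target_id, "microsite"])
    score = pct + 100.0 * r2 + (100.0 if same else 0.0)
    return PairStats(
        target_id=target_id,
        donor_id=donor_id,
        n_common=n_common,
        pct_valid_common=pct,
        r=r,
        r_squared=r2,
        same_microsite=same,
        score=score,
        eligible=eligible,
    )


def rank_donors(
    table: pd.DataFrame,
    meta: list[SensorMeta],
    target_id: str,
    min_overlap: int = 100,
) -> list[PairStats]:
    """All eligible donors for ``target_id``, best first.

    Sorted by score descending; ties broken by higher ``pct_valid_common``,
    then lexicographic donor id.  Donors with fewer than ``min_overlap``
    common cases, or an undefined correlation, are excluded — the list may
    be empty.
    """
    cands = [
        pair_statistics(table, meta, donor_id, target_id)
        for donor_id in table.columns
        if donor_id != target_id
    ]
    cands = [c for c in cands if c.eligible and c.n_common >= min_overlap]
    cands.sort(key=lambda c: (-c.score, -c.pct_valid_common, c.donor_id))
    return cands


def fit_donor_model(
    table: pd.DataFrame,
    donor_id: str,
    target_id: str,
    min_overlap: int = 100,
) -> LinearFit:
    """OLS fit of the target on the donor over their common valid cases."""
    if donor_id == target_id:
        raise EligibilityError(f"donor and target are the same sensor ({donor_id!r})")
    x = table[donor_id].to_numpy(dtype=float)
    y = table[target_id].to_numpy(dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < max(min_overlap, 2):
        raise EligibilityError(
            f"pair ({donor_id!r} -> {target_id!r}) has only {n} common cases "
            f"(min_overlap={min_overlap})"
        )
    xx, yy = x[both], y[both]
    if np.ptp(xx) == 0:
        raise EligibilityError(
            f"donor {donor_id!r} is constant on the overlap with {target_id!r}"
        )
    res = stats.linregress(xx, yy)
    return LinearFit(
        target_id=target_id,
        donor_id=donor_id,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        n=n,
    )


def impute_table(
    table: pd.DataFrame,
    meta: list[SensorMeta],
    config: ImputeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ImputationReport]:
    """Fill the gaps of a QC'd sensor table by donor regression.

    For each missing cell the donor ranking for its sensor is walked in
    order; the first donor observed at that timestamp supplies the model
    prediction.  Observed cells are never modified.  Returns the filled
    table, the quality grid (1 = observed, model r = imputed, missing =
    unfilled) and a report whose ``gap_log`` has one row per filled cell
    (timestamp, target, donor, score, r).
    """
    config = config or ImputeConfig()
    if config.min_overlap < 2:
        raise ConfigurationError(f"min_overlap must be >= 2, got {config.min_overlap}")
    validate_table(table)

    filled = table.copy()
    quality = pd.DataFrame(
        np.where(table.notna(), 1.0, np.nan), index=table.index, columns=table.columns
    )
    n_before = int(table.isna().to_numpy().sum())

    # rankings and fits come from the original observed record only:
    # one model per (donor, target) pair, reused for every gap it serves
    rankings = {
        t: rank_donors(table, meta, t, min_overlap=config.min_overlap)
        for t in table.columns
    }
    fits: dict[tuple[str, str], LinearFit] = {}

    def get_fit(donor_id: str, target_id: str) -> LinearFit:
        key = (donor_id, target_id)
        if key not in fits:
            fits[key] = fit_donor_model(
                table, donor_id, target_id, min_overlap=config.min_overlap
            )
        return fits[key]

    log_rows: list[dict] = []
    donor_pool = table  # pass 1: only originally observed values may donate
    while True:
        n_filled_this_pass = 0
        next_filled = filled.copy()
        for target_id in table.columns:
            still_missing = filled[target_id].isna()
            if not still_missing.any():
                continue
            for ps in rankings[target_id]:
                if not still_missing.any():
                    break
                use = still_missing & donor_pool[ps.donor_id].notna()
                if not use.any():
                    continue
                fit = get_fit(ps.donor_id, target_id)
                pred = fit.predict(donor_pool.loc[use, ps.donor_id].to_numpy())
                if config.clip:
                    pred = np.clip(pred, 0.0, 1.0)
                next_filled.loc[use, target_id] = pred
                quality.loc[use, target_id] = fit.r
                for t in table.index[use.to_numpy()]:
                    log_rows.append(
                        {
                            "timestamp": t,
                            "target_id": target_id,
                            "donor_id": ps.donor_id,
                            "score": ps.score,
                            "r": fit.r,
                        }
                    )
                n_filled_this_pass += int(use.sum())
                still_missing = still_missing & ~use
        filled = next_filled
        if not config.iterative or n_filled_this_pass == 0:
            break
        donor_pool = filled  # later passes may chain through imputed donors

    n_after = int(filled.isna().to_numpy().sum())
    gap_log = pd.DataFrame(
        log_rows, columns=["timestamp", "target_id", "donor_id", "score", "r"]
    )
    report = ImputationReport(
        n_missing_before=n_before,
        n_filled=n_before - n_after,
        n_missing_after=n_after,
        gap_log=gap_log,
    )
    return filled, quality, report
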