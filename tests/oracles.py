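"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops and textbook formulas, on
purpose: these functions re-derive the selection score, donor ranking, OLS
coefficients and slope confidence intervals from first principles so the
package implementation can be checked against them.  They share no code
with soilgaps.
"""

from __future__ import annotations

import math


def brute_pair_stats(values, microsites, donor, target, n_timestamps):
    """Selection-score statistics for one ordered pair.

    ``values`` maps sensor id -> list of floats/None (None = missing);
    ``microsites`` maps sensor id -> microsite label.
    Returns dict with n_common, pct_valid_common, r, r_squared,
    same_microsite, score, eligible.
    """
    xs, ys = [], []
    for xv, yv in zip(values[donor], values[target]):
        if xv is not None and yv is not None:
            xs.append(xv)
            ys.append(yv)
    n = len(xs)
    pct = 100.0 * n / n_timestamps
    eligible = n >= 2 and max(xs, default=0) > min(xs, default=0) and max(
        ys, default=0
    ) > min(ys, default=0)
    if eligible:
        mx = sum(xs) / n
        my = sum(ys) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        sxx = sum((a - mx) ** 2 for a in xs)
        syy = sum((b - my) ** 2 for b in ys)
        r = sxy / math.sqrt(sxx * syy)
        r2 = r * r
    else:
        r, r2 = 0.0, 0.0
    same = microsites[donor] == microsites[target]
    score = pct + 100.0 * r2 + (100.0 if same else 0.0)
    return {
        "n_common": n,
        "pct_valid_common": pct,
        "r": r,
        "r_squared": r2,
        "same_microsite": same,
        "score": score,
        "eligible": eligible,
    }


def brute_rank(values, microsites, target, n_timestamps, min_overlap):
    """Eligible donors for ``target``, best first, honoring the tie rules."""
    cands = []
    for donor in values:
        if donor == target:
            continue
        ps = brute_pair_stats(values, microsites, donor, target, n_timestamps)
        if ps["eligible"] and ps["n_common"] >= min_overlap:
            cands.append((donor, ps))
    cands.sort(key=lambda c: (-c[1]["score"], -c[1]["pct_valid_common"], c[0]))
    return cands


def brute_donor_choice(values, microsites, target, t, n_timestamps, min_overlap):
    """Exhaustive best donor for the gap (t, target), or None.

    The donor must be observed at t and have an eligible fit; among those,
    maximize score with ties broken by pct_valid_common then donor id.
    """
    for donor, ps in brute_rank(values, microsites, target, n_timestamps, min_overlap):
        if values[donor][t] is not None:
            return donor
    return None


def brute_ols(xs, ys):
    """Normal-equation OLS of y on x: returns (intercept, slope)."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(a * a for a in xs)
    sxy = sum(a * b for a, b in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def brute_slope_ci(xs, ys, tq):
    """Slope with its two-sided CI given the t quantile ``tq`` (df = n-2)."""
    n = len(xs)
    intercept, slope = brute_ols(xs, ys)
    resid = [y - (intercept + slope * x) for x, y in zip(xs, ys)]
    sse = sum(e * e for e in resid)
    mx = sum(xs) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    se = math.sqrt(sse / (n - 2) / sxx)
    return slope, slope - tq * se, slope + tq * se
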