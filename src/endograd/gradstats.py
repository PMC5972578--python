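"""Fixed-effects gradient statistics.

Linear trends of calibrated protein concentration against mid-band distance,
and of log protein-body area against body distance, fitted per treatment
group by ordinary least squares.  A distance-squared lack-of-fit check
(nested-model F test) guards the linearity assumption.  Group comparisons
are descriptive Welch-type contrasts of slopes; inference with the full
nested random-effects structure (blocks / pots / section and analysis
replicates) belongs in dedicated mixed-model software, for which the tidy
tables exported here are the input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bodymetrics import ProteinBody


@dataclass
class GradientFit:
    """One per-group OLS trend of a response against distance (micrometres)."""

    group: tuple
    response: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int
    r2: float
    quad_p: float | None = None


def fit_gradient(distances, responses, group: tuple = (),
                 response: str = "concentration") -> GradientFit:
    """Ordinary least-squares line of response on distance.

    Requires at least 3 observations and a non-degenerate design (distances
    not all equal).
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("distances and responses must be matching 1-D arrays")
    if len(x) < 3:
        raise ValueError(f"need >= 3 observations for a fit, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all distances equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared) if model.centered_tss > 0 else 1.0
    return GradientFit(
        group=tuple(group), response=response,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_se=float(model.bse[1]), intercept_se=float(model.bse[0]),
        n=len(x), r2=max(0.0, min(1.0, r2)),
    )


def log_transform_areas(bodies: list[ProteinBody]) -> tuple[np.ndarray, np.ndarray]:
    """(distance_um, ln area_um2) observation pairs for body-size trends.

    Natural log stabilises the strongly right-skewed body-area variance;
    report back-transformed means with ``np.exp`` when presenting results.
    """
    if not bodies:
        raise ValueError("no bodies to transform")
    areas = np.array([b.area for b in bodies], dtype=float)
    dists = np.array([b.distance for b in bodies], dtype=float)
    if np.any(~np.isfinite(dists)):
        raise ValueError("bodies must have distances assigned first")
    if np.any(areas <= 0):
        raise ValueError("non-positive body area")
    return dists, np.log(areas)


def quadratic_check(distances, responses, fit: GradientFit) -> GradientFit:
    """Nested-model F test for curvature: linear vs linear + distance^2.

    F = ((RSS_lin - RSS_quad) / 1) / (RSS_quad / (n - 3)); the updated fit
    carries the p-value in ``quad_p``.  The model is never switched
    automatically — a small p flags non-linearity for the analyst.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 observations for the curvature check")
    X1 = sm.add_constant(x)
    X2 = np.column_stack([X1, x ** 2])
    rss1 = float(sm.OLS(y, X1).fit().ssr)
    rss2 = float(sm.OLS(y, X2).fit().ssr)
    df2 = len(x) - 3
    gain = max(rss1 - rss2, 0.0)
    scale = max(rss1, 1.0)
    if gain <= 1e-12 * scale:  # exactly linear data: no curvature evidence
        return replace(fit, quad_p=1.0)
    f_stat = gain / (rss2 / df2) if rss2 > 0 else np.inf
    return replace(fit, quad_p=float(stats.f.sf(f_stat, 1, df2)))


def compare_groups(fits: list[GradientFit]) -> pd.DataFrame:
    """Pairwise slope contrasts between group fits (descriptive).

    Welch-type z statistics difference / sqrt(se_a^2 + se_b^2) with normal
    p-values; these ignore the experiment's nesting structure and are meant
    for screening, not confirmatory inference.
    """
    if len(fits) < 2:
        raise ValueError(">= 2 groups required")
    rows = []
    for a, b in combinations(fits, 2):
        diff = a.slope - b.slope
        se = float(np.hypot(a.slope_se, b.slope_se))
        z = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
        rows.append({
            "group_a": "/".join(map(str, a.group)) or "a",
            "group_b": "/".join(map(str, b.group)) or "b",
            "response": a.response,
            "slope_a": a.slope, "slope_b": b.slope,
            "slope_diff": diff, "diff_se": se,
            "z": z, "p_normal": float(2 * stats.norm.sf(abs(z))),
        })
    return pd.DataFrame(rows)


def fits_to_frame(fits: list[GradientFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": "/".join(map(str, f.group)),
        "response": f.response,
        "slope": f.slope, "slope_se": f.slope_se,
        "intercept": f.intercept, "intercept_se": f.intercept_se,
        "n": f.n, "r2": f.r2, "quad_p": f.quad_p,
    } for f in fits])
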