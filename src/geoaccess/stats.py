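"""Population-weighted accessibility statistics for adults aged 60+.

Given the 1 km travel-time raster and the 1 km population raster, this module
computes the summaries used to describe access to care: the share of the
population beyond a travel-time cut-off (with a Wilson score 95% CI), the
population-weighted distribution of travel time, the median and IQR of the
worst-off fifth of the population, and categorical maps over populated areas
(cells with at least one adult aged 60+ per km²).

Cut-off conventions
-------------------
Hospital access uses categories <2 h, 2–6 h, 6–12 h, >12 h (boundaries 120,
360, 720 min); any-facility access uses <1 h, 1–2 h, 2–6 h, >6 h (60, 120,
360 min).  Categories are closed on the left: a cell at exactly 120 min falls
in the 2–6 h category.  Unreachable cells count above every cut-off and in
the open-ended top category.

Wilson denominator
------------------
The Wilson interval needs a binomial denominator *n*.  Raster population
counts are not n independent Bernoulli draws, so *n* is an explicit,
mandatory argument: pass an effective sample size, or the string
``"populated_cells"`` to use the number of populated 1 km cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Raster

__all__ = [
    "CutoffScheme",
    "HOSPITAL_SCHEME",
    "ANY_FACILITY_SCHEME",
    "ProportionEstimate",
    "AccessSummary",
    "wilson_interval",
    "proportion_above",
    "weighted_quantile",
    "weighted_quantile_stats",
    "categorize_map",
    "distribution_table",
    "summarize_access",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CutoffScheme:
    """Ordered travel-time boundaries (minutes) defining the map categories."""

    name: str
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if not b or any(x <= 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be positive and strictly increasing")

    @property
    def labels(self) -> list[str]:
        def fmt(minutes: float) -> str:
            return f"{minutes / 60:g}h" if minutes % 60 == 0 else f"{minutes:g}min"

        b = self.boundaries
        labels = [f"<{fmt(b[0])}"]
        labels += [f"{fmt(lo)}-{fmt(hi)}" for lo, hi in zip(b[:-1], b[1:])]
        labels.append(f">{fmt(b[-1])}")
        return labels

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1


HOSPITAL_SCHEME = CutoffScheme("hospital", (120.0, 360.0, 720.0))
ANY_FACILITY_SCHEME = CutoffScheme("any_facility", (60.0, 120.0, 360.0))


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its Wilson score interval."""

    p_hat: float
    n: float
    ci_low: float
    ci_high: float
    z: float = Z_95

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0:
            raise ValueError("need 0 <= ci_low <= p_hat <= ci_high <= 1")


def wilson_interval(p_hat: float, n: float, z: float = Z_95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    center = (p̂ + z²/2n) / (1 + z²/n);
    half-width = z·sqrt(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n); clipped to [0, 1].
    Well-behaved near 0 and 1, unlike the Wald interval.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    z2n = z * z / n
    denom = 1.0 + z2n
    center = (p_hat + z2n / 2.0) / denom
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z2n / (4.0 * n)) / denom
    # the score interval always contains p-hat; guard against the last-ulp
    # rounding of center +/- half at the degenerate proportions
    lo = min(max(0.0, center - half), p_hat)
    hi = max(min(1.0, center + half), p_hat)
    return lo, hi


def _finite_weights(tt: Raster, pop: Raster) -> tuple[np.ndarray, np.ndarray]:
    """(travel time, population) over cells with population and non-nodata time."""
    if tt.grid != pop.grid:
        raise ValueError("travel-time and population rasters must share one grid")
    t = np.asarray(tt.values, dtype=float).ravel()
    w = np.asarray(pop.values, dtype=float).ravel()
    keep = ~np.isnan(t) & ~np.isnan(w) & (w > 0)
    return t[keep], w[keep]


def proportion_above(
    tt: Raster,
    pop: Raster,
    cutoff: float,
    ci_n: float | str = "populated_cells",
    z: float = Z_95,
) -> ProportionEstimate:
    """Population share with travel time above ``cutoff`` minutes.

    Unreachable cells (+inf) lie above any cut-off.  ``ci_n`` sets the Wilson
    denominator: a number (effective sample size) or ``"populated_cells"``
    for the count of 1 km cells with at least one person.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    t, w = _finite_weights(tt, pop)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total population")
    p_hat = float(w[t > cutoff].sum() / total)
    n = float(len(t)) if ci_n == "populated_cells" else float(ci_n)
    lo, hi = wilson_interval(p_hat, n, z)
    return ProportionEstimate(p_hat, n, lo, hi, z)


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Weighted quantiles, linear on the mid-cumulative weight (Hazen rule).

    Sorted values x_i with weights w_i get plotting positions
    F_i = (cum_i − w_i/2) / W; quantiles interpolate linearly between the
    (F_i, x_i) points and clamp to the extremes outside [F_1, F_k].  With unit
    weights this reproduces the classic midpoint convention (e.g. the median
    of 1..20 is 10.5).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take quantiles of an empty distribution")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    positions = (cum - w / 2.0) / cum[-1]
    return np.interp(q, positions, v)


def weighted_quantile_stats(
    tt: Raster,
    pop: Raster,
    quantile_band: tuple[float, float] = (0.8, 1.0),
    include_unreachable: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Median and IQR (minutes) of a population-weighted travel-time band.

    The default band [0.8, 1.0] is the worst-off fifth: cells are sorted by
    travel time, the top 20% of the population mass is taken (splitting the
    boundary cell's weight exactly), and the weighted median and (Q1, Q3) of
    that sub-population are returned.  With ``include_unreachable`` (default)
    unreachable cells enter as +inf, so a quantile landing on them is
    reported as inf ("unreachable"); otherwise they are dropped first.
    """
    lo_q, hi_q = quantile_band
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError(f"quantile band must satisfy 0 <= lo < hi <= 1, got {quantile_band}")
    t, w = _finite_weights(tt, pop)
    if not include_unreachable:
        keep = np.isfinite(t)
        t, w = t[keep], w[keep]
    if w.sum() <= 0:
        raise ValueError("zero total population in the requested band")
    order = np.argsort(t, kind="stable")
    t, w = t[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    lo_mass, hi_mass = lo_q * total, hi_q * total
    # clip each cell's weight to the band of cumulative mass, splitting edges
    band_w = np.maximum(0.0, np.minimum(cum, hi_mass) - np.maximum(cum - w, lo_mass))
    keep = band_w > 0
    t_band, w_band = t[keep], band_w[keep]
    if np.isinf(t_band).all():
        return float("inf"), (float("inf"), float("inf"))
    med, q1, q3 = weighted_quantile(t_band, w_band, [0.5, 0.25, 0.75])
    return float(med), (float(q1), float(q3))


def categorize_map(tt: Raster, pop: Raster, scheme: CutoffScheme) -> Raster:
    """Categorical travel-time raster over populated areas.

    Cells with at least 1 person get the 0-based category index from the
    scheme (closed-left bins, unreachable in the top category); cells with
    fewer than 1 person, or nodata travel time, are masked (NaN).
    """
    if tt.grid != pop.grid:
        raise ValueError("travel-time and population rasters must share one grid")
    t = np.asarray(tt.values, dtype=float)
    cat = np.full(t.shape, np.nan)
    populated = ~np.isnan(np.asarray(pop.values, dtype=float)) & (pop.values >= 1.0)
    valid = populated & ~np.isnan(t)
    # closed-left: value exactly at a boundary goes to the upper category
    cat[valid] = np.searchsorted(np.asarray(scheme.boundaries), t[valid], side="right")
    return Raster(tt.grid, cat)


def distribution_table(
    tt: Raster, pop: Raster, bin_width: float = 30.0, max_minutes: float | None = None
) -> pd.DataFrame:
    """Population-weighted histogram of travel time.

    Bins are [k·width, (k+1)·width) plus one final open-ended bin that also
    holds the unreachable population; bin masses sum to the total population.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    t, w = _finite_weights(tt, pop)
    finite = np.isfinite(t)
    if max_minutes is None:
        max_minutes = float(t[finite].max()) if finite.any() else 0.0
    n_bins = max(1, int(np.ceil(max_minutes / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum(np.floor(t[finite] / bin_width).astype(int), n_bins)
    counts = np.bincount(idx, weights=w[finite], minlength=n_bins + 1)
    counts[n_bins] += w[~finite].sum()
    left = np.append(edges[:-1], edges[-1])
    right = np.append(edges[1:], np.inf)
    return pd.DataFrame({"bin_left_min": left, "bin_right_min": right, "population": counts})


@dataclass
class AccessSummary:
    """Per-region population-weighted access summary."""

    region: str
    total_population: float
    scheme: CutoffScheme
    category_shares: list[float]
    proportions_above: dict[float, ProportionEstimate]
    worst_quintile_median: float
    worst_quintile_iqr: tuple[float, float]
    share_unreachable: float
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {"region": self.region, "total_pop": self.total_population}
        for label, share in zip(self.scheme.labels, self.category_shares):
            row[f"share_{label}"] = share
        cutoff = self.scheme.boundaries[-1]
        est = self.proportions_above[cutoff]
        row.update(
            p_above_cutoff=est.p_hat,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
            q5_median_min=self.worst_quintile_median,
            q5_iqr_low=self.worst_quintile_iqr[0],
            q5_iqr_high=self.worst_quintile_iqr[1],
            share_unreachable=self.share_unreachable,
        )
        return row


def summarize_access(
    tt: Raster,
    pop: Raster,
    scheme: CutoffScheme,
    ci_n: float | str = "populated_cells",
    region: str = "all",
    regions: dict | None = None,
) -> list[AccessSummary]:
    """Full access summary, overall or per region polygon.

    With ``regions`` (name -> shapely polygon), 1 km cells are attributed by
    cell-center point-in-polygon and one summary is produced per region; the
    headline proportion-above uses the scheme's top boundary as cut-off.
    """
    if regions:
        out = []
        xx, yy = tt.grid.cell_centers()
        import shapely

        for name, poly in regions.items():
            inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(tt.grid.shape)
            masked_pop = Raster(pop.grid, np.where(inside, pop.values, 0.0))
            out.extend(summarize_access(tt, masked_pop, scheme, ci_n, region=name))
        return out

    t, w = _finite_weights(tt, pop)
    total = float(w.sum())
    if total <= 0:
        raise ValueError(f"region {region!r} has zero population")
    bounds = np.asarray(scheme.boundaries)
    cat = np.searchsorted(bounds, t, side="right")
    shares = [float(w[cat == k].sum() / total) for k in range(scheme.n_categories)]
    props = {
        float(b): proportion_above(tt, pop, float(b), ci_n=ci_n) for b in scheme.boundaries
    }
    med, iqr = weighted_quantile_stats(tt, pop)
    return [
        AccessSummary(
            region=region,
            total_population=total,
            scheme=scheme,
            category_shares=shares,
            proportions_above=props,
            worst_quintile_median=med,
            worst_quintile_iqr=iqr,
            share_unreachable=float(w[np.isinf(t)].sum() / total),
        )
    ]
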