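"""Per-walk summary statistics and circular statistics for walk azimuths.

For each walk we report the *total distance* (accumulated centre-to-centre
path length), the *resultant distance* (straight-line start-to-end
distance), the *walk deviation* ``100 * (total - resultant) / total`` —
the percentage by which the walk departs from a straight line — and the
*azimuth* of the resultant, a compass bearing in degrees clockwise from
grid north computed by the surveyors' quadrant method.

Across a batch, azimuths are tested for departure from circular uniformity
with the Rayleigh test (powerful against unimodal alternatives) and the
Stephens-modified Kuiper test (rotation-invariant, sensitive to multimodal
alternatives).  Rose-diagram helpers bin azimuths into equal sectors and
report square-root-scaled heights, so petal *area* is proportional to
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .walker import Walk

__all__ = [
    "WalkStats",
    "CircularTestResult",
    "walk_distances",
    "azimuth",
    "rayleigh_test",
    "kuiper_test",
    "kuiper_pvalue",
    "rose_bins",
    "stats_table",
]


@dataclass(frozen=True)
class WalkStats:
    """Distance and direction summary of one walk.

    ``azimuth_deg`` is ``None`` (undefined) exactly when the walk returns
    to its starting point (zero resultant).
    """

    total_distance: float
    resultant_distance: float
    deviation_pct: float
    azimuth_deg: float | None


@dataclass(frozen=True)
class CircularTestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def walk_distances(walk: Walk) -> WalkStats:
    """Total, resultant and deviation (and azimuth) for one walk.

    Deviation of a zero-length walk is defined as 0% — a walk that never
    moved deviates from nothing.
    """
    total = float(walk.step_lengths.sum())
    x0, y0 = walk.centres[0]
    x1, y1 = walk.centres[-1]
    resultant = math.hypot(x1 - x0, y1 - y0)
    deviation = 100.0 * (total - resultant) / total if total > 0 else 0.0
    return WalkStats(
        total_distance=total,
        resultant_distance=resultant,
        deviation_pct=deviation,
        azimuth_deg=azimuth((x0, y0), (x1, y1)),
    )


def azimuth(
    start: tuple[float, float], end: tuple[float, float]
) -> float | None:
    """Quadrant-method bearing from ``start`` to ``end``.

    Degrees clockwise from grid north in [0, 360).  The base angle is
    ``arctan(|dE| / |dN|)`` and the quadrant correction is NE: theta,
    SE: 180 - theta, SW: 180 + theta, NW: 360 - theta.  Zero displacement
    has no bearing and returns ``None``.
    """
    de = end[0] - start[0]
    dn = end[1] - start[1]
    if de == 0 and dn == 0:
        return None
    if dn == 0:
        theta = 90.0
    else:
        theta = math.degrees(math.atan(abs(de) / abs(dn)))
    if de >= 0 and dn > 0:      # NE
        bearing = theta
    elif de > 0 and dn <= 0:    # SE
        bearing = 180.0 - theta
    elif de <= 0 and dn < 0:    # SW
        bearing = 180.0 + theta
    else:                       # NW
        bearing = 360.0 - theta
    return bearing % 360.0


def rayleigh_test(azimuths_deg) -> CircularTestResult:
    """Rayleigh test of circular uniformity against a unimodal alternative.

    Statistic ``Z = n * Rbar**2`` where ``Rbar`` is the mean resultant
    length; the p-value uses the standard small-sample series
    ``p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4) /
    (288 n^2)]``, clipped to [0, 1].
    """
    a = np.asarray(azimuths_deg, dtype=float)
    if a.size == 0:
        raise ValueError("rayleigh_test requires at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    n = a.size
    th = np.deg2rad(a)
    rbar = abs(np.exp(1j * th).sum()) / n
    z = n * rbar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return CircularTestResult(
        statistic=float(z), p_value=float(min(max(p, 0.0), 1.0)), n=n,
        method="rayleigh",
    )


def kuiper_pvalue(vstar: float) -> float:
    """Tail probability of the Stephens-modified Kuiper statistic.

    ``p = sum_{k>=1} 2 (4 k^2 V*^2 - 1) exp(-2 k^2 V*^2)``, truncated when
    a term drops below 1e-10, clipped to [0, 1].
    """
    p = 0.0
    for k in range(1, 200):
        t = k * k * vstar * vstar
        term = 2.0 * (4.0 * t - 1.0) * math.exp(-2.0 * t)
        p += term
        if abs(term) < 1e-10:
            break
    return min(max(p, 0.0), 1.0)


def kuiper_test(azimuths_deg) -> CircularTestResult:
    """Stephens-modified Kuiper test of circular uniformity.

    The raw statistic is ``V = D+ + D-`` of the angles mapped to [0, 1)
    via ``theta / 360`` against the uniform CDF; the reported statistic is
    the sample-size-stabilised ``V* = V * (sqrt(n) + 0.155 + 0.24 /
    sqrt(n))``.  Unlike Kolmogorov-Smirnov, V is invariant under rotation
    of all angles by any constant, which makes the test origin-free on the
    circle.  Requires n >= 5 (the asymptotic p-value series is unreliable
    below that).
    """
    a = np.asarray(azimuths_deg, dtype=float)
    n = a.size
    if n < 5:
        raise ValueError("kuiper_test requires n >= 5")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    u = np.sort((a % 360.0) / 360.0)
    i = np.arange(1, n + 1)
    dplus = np.max(i / n - u)
    dminus = np.max(u - (i - 1) / n)
    v = dplus + dminus
    vstar = v * (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n))
    return CircularTestResult(
        statistic=float(vstar), p_value=kuiper_pvalue(float(vstar)), n=int(n),
        method="kuiper_modified",
    )


def rose_bins(azimuths_deg, bin_width: float) -> np.ndarray:
    """Square-root-scaled rose-diagram bin heights.

    Counts angles into half-open sectors ``[k*w, (k+1)*w)`` (360 wraps to
    bin 0) and returns ``sqrt(count)`` per bin, so ``sum(height**2)``
    recovers the sample size.  ``bin_width`` must divide 360 exactly.
    """
    if bin_width <= 0 or not math.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ValueError(f"bin_width must divide 360 exactly, got {bin_width}")
    nbins = int(round(360.0 / bin_width))
    a = np.asarray(azimuths_deg, dtype=float)
    heights = np.zeros(nbins)
    if a.size:
        idx = np.floor((a % 360.0) / bin_width).astype(int) % nbins
        counts = np.bincount(idx, minlength=nbins)
        heights = np.sqrt(counts.astype(float))
    return heights


def stats_table(walks: list[Walk]) -> pd.DataFrame:
    """One row of WalkStats per walk (run id, seed, status, distances)."""
    rows = []
    for k, w in enumerate(walks):
        s = walk_distances(w)
        rows.append(
            {
                "run": k,
                "seed": repr(w.seed_record),
                "status": w.status,
                "n_steps": w.n_steps,
                "total_distance": s.total_distance,
                "resultant_distance": s.resultant_distance,
                "deviation_pct": s.deviation_pct,
                "azimuth_deg": s.azimuth_deg,
                "n_fallback_events": len(w.fallback_steps),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "run", "seed", "status", "n_steps", "total_distance",
            "resultant_distance", "deviation_pct", "azimuth_deg",
            "n_fallback_events",
        ],
    )
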