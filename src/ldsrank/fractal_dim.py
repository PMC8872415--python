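"""Local fractal dimension (LFD) and local fuzzy fractal dimension (LFFD).

Both dimensions describe how fast the neighborhood of a node grows with
the topological radius r.  For a node v with sphere count B_v(r) -- the
number of nodes within hop distance r of v, center included -- a
power-law growth B_v(r) = C * r^D_v makes D_v the slope of ln B_v(r)
against ln r.  That slope is the local fractal dimension.

The fuzzy variant replaces the raw count with a mean Gaussian
membership: each node j within radius r contributes

    A_vj(r) = exp(-d_vj^2 / (2 r^2)),

so nearby nodes weigh more than boundary nodes, and

    N_v(r) = mean of A_vj(r) over all j with d_vj <= r  (center included).

The LFFD D_f(v) is the slope of ln N_v(r) against ln r.

Fit convention
--------------
Unweighted ordinary least squares on (ln r, ln y) over every radius
r = 1..eccentricity(v), including the r = 1 point (where ln r = 0); no
point dropping, no weighting, natural logarithms throughout.  Nodes
whose eccentricity is below 2 yield fewer than two fit points; their
dimension is defined as 0.0 (logged as a warning) so that such proteins
rank lowest on the topological signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ldsrank.graph_io import single_source_distances

log = logging.getLogger(__name__)


class UnfittableError(ValueError):
    """Raised when a log-log fit has fewer than two usable points."""


@dataclass(frozen=True)
class FractalFit:
    """Result of a log-log least-squares fit.

    ``slope`` is the fitted dimension; ``intercept`` is ln C of the
    power law, in natural log units.
    """

    points: tuple[tuple[int, float], ...]
    slope: float
    intercept: float

    @property
    def n_points(self) -> int:
        return len(self.points)


def sphere_counts(profile: Mapping[str, int]) -> list[int]:
    """Cumulative sphere counts B(r) for r = 1..eccentricity.

    ``profile`` is a distance map as produced by
    :func:`ldsrank.graph_io.single_source_distances`; the center (d = 0)
    is counted in every sphere.  An isolated center yields an empty list.
    """
    dists = sorted(profile.values())
    ecc = dists[-1]
    return [sum(1 for d in dists if d <= r) for r in range(1, ecc + 1)]


def gaussian_membership(d: float, r: float) -> float:
    """Gaussian membership exp(-d^2 / (2 r^2)) of a node at distance d."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return math.exp(-(d * d) / (2.0 * r * r))


def fuzzy_sphere_value(profile: Mapping[str, int], r: int) -> float:
    """Mean Gaussian membership N(r) over nodes within radius r.

    Averages exp(-d^2/(2r^2)) over every node at distance <= r from the
    center, the center itself (d = 0, membership 1) included.
    """
    members = [d for d in profile.values() if d <= r]
    return sum(gaussian_membership(d, r) for d in members) / len(members)


def fuzzy_sphere_values(profile: Mapping[str, int]) -> list[float]:
    """N(r) for every radius r = 1..eccentricity of the profile."""
    ecc = max(profile.values())
    return [fuzzy_sphere_value(profile, r) for r in range(1, ecc + 1)]


def loglog_slope(points: Iterable[tuple[float, float]]) -> FractalFit:
    """Ordinary least-squares fit of ln y against ln r.

    Raises :class:`UnfittableError` for fewer than two distinct radii and
    ``ValueError`` for any non-positive y.
    """
    pts = sorted((r, y) for r, y in points)
    if any(y <= 0 for _, y in pts):
        raise ValueError("all y values must be positive for a log-log fit")
    if len({r for r, _ in pts}) < 2:
        raise UnfittableError(
            f"need >= 2 points with distinct radii, got {len(pts)}"
        )
    x = np.log([r for r, _ in pts])
    y = np.log([y for _, y in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return FractalFit(points=tuple(pts), slope=float(slope), intercept=float(intercept))


def _dimension(values: Sequence[float], v: str, label: str) -> float:
    try:
        fit = loglog_slope((r, y) for r, y in enumerate(values, start=1))
    except UnfittableError:
        log.warning("%s unfittable for %r (eccentricity < 2); using 0.0", label, v)
        return 0.0
    return fit.slope


def lfd(net: nx.Graph, v: str) -> float:
    """Local fractal dimension of node ``v``: OLS slope of ln B(r) vs ln r."""
    counts = sphere_counts(single_source_distances(net, v))
    return _dimension(counts, v, "LFD")


def lffd(net: nx.Graph, v: str) -> float:
    """Local fuzzy fractal dimension of ``v``: OLS slope of ln N(r) vs ln r."""
    values = fuzzy_sphere_values(single_source_distances(net, v))
    return _dimension(values, v, "LFFD")


def lfd_all(net: nx.Graph) -> dict[str, float]:
    """LFD for every node of the network."""
    return {v: lfd(net, v) for v in net.nodes()}


def lffd_all(net: nx.Graph) -> dict[str, float]:
    """LFFD for every node of the network."""
    return {v: lffd(net, v) for v in net.nodes()}
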