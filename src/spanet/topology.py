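"""Topological characterization: power-law fits, global statistics, hubs.

The degree distribution P(k) and the degree-conditional mean clustering
coefficient C(k) are fitted with ordinary least squares on log10-log10
axes, on the raw (non-binned, non-cumulative) empirical points — the R² of
that linear regression is the reported goodness of fit.  A negative fitted
slope of magnitude γ for P(k) indicates a scale-free regime; a power-law
decay C(k) ~ k^-w marks a hierarchical (modular) organization.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import MissingProteinError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) = intercept - exponent * log10(x)."""

    exponent: float
    intercept: float
    r2: float
    support: tuple[float, ...]  # abscissae used

    @property
    def n_points(self) -> int:
        return len(self.support)


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y ~ c * x^-exponent by OLS on log-log axes.

    Requires >= 3 distinct positive abscissae with positive ordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if len(set(x.tolist())) < 3:
        raise ParameterError("power-law fit requires >=3 distinct positive abscissae")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        exponent=-float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        support=tuple(sorted(set(x.tolist()))),
    )


def degree_distribution(g: nx.Graph) -> dict[int, float]:
    """Empirical P(k) over observed degrees k >= 1 (normalized by |V|)."""
    n = g.number_of_nodes()
    counts = Counter(d for _, d in g.degree if d >= 1)
    return {k: c / n for k, c in sorted(counts.items())}


def degree_fit(g: nx.Graph) -> PowerLawFit:
    """Power-law fit of the raw degree distribution; returns γ = -slope."""
    pk = degree_distribution(g)
    return fit_power_law(list(pk), list(pk.values()))


def clustering_spectrum(g: nx.Graph) -> dict[int, float]:
    """C(k): mean local clustering coefficient among degree-k nodes (k >= 2)."""
    cc = nx.clustering(g)
    acc: dict[int, list[float]] = {}
    for v, d in g.degree:
        if d >= 2:
            acc.setdefault(d, []).append(cc[v])
    return {k: float(np.mean(vals)) for k, vals in sorted(acc.items())}


def clustering_spectrum_fit(g: nx.Graph) -> PowerLawFit:
    """Power-law fit of C(k); returns w = -slope.

    Degree classes with zero mean clustering are excluded (no logarithm);
    a triangle-free graph therefore raises a parameter error.
    """
    ck = {k: c for k, c in clustering_spectrum(g).items() if c > 0}
    if len(ck) < 3:
        raise ParameterError(
            "clustering spectrum fit requires >=3 degree classes with positive C(k)"
        )
    return fit_power_law(list(ck), list(ck.values()))


@dataclass(frozen=True)
class TopologySummary:
    """Global statistics mirroring the standard PPI-network summary table."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    cpl: float          # mean shortest-path length over connected ordered pairs
    diameter: int       # max eccentricity on the largest component
    avg_clustering: float
    degree_fit: PowerLawFit | None = None
    clustering_fit: PowerLawFit | None = None

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "cpl": self.cpl,
            "diameter": self.diameter,
            "avg_clustering": self.avg_clustering,
        }
        for name, fit in (("degree_fit", self.degree_fit),
                          ("clustering_fit", self.clustering_fit)):
            d[name] = (
                None
                if fit is None
                else {"exponent": fit.exponent, "r2": fit.r2, "n_points": fit.n_points}
            )
        return d


def summary(g: nx.Graph, fits: bool = True) -> TopologySummary:
    """Compute the summary statistics of a (possibly disconnected) network.

    The critical path length averages shortest-path lengths over connected
    ordered pairs within components; the diameter is taken on the largest
    component.  Nodes of degree < 2 contribute 0 to the mean clustering
    coefficient.
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ParameterError("summary of an empty graph")
    comps = [g.subgraph(c) for c in nx.connected_components(g)]
    total_len = 0.0
    total_pairs = 0
    for c in comps:
        nc = c.number_of_nodes()
        if nc >= 2:
            pairs = nc * (nc - 1)
            total_len += nx.average_shortest_path_length(c) * pairs
            total_pairs += pairs
    cpl = total_len / total_pairs if total_pairs else 0.0
    largest = max(comps, key=lambda c: c.number_of_nodes())
    diam = nx.diameter(largest) if largest.number_of_nodes() > 1 else 0

    deg_fit = clust_fit = None
    if fits:
        try:
            deg_fit = degree_fit(g)
        except ParameterError:
            logger.info("degree distribution not fittable for this graph")
        try:
            clust_fit = clustering_spectrum_fit(g)
        except ParameterError:
            logger.info("clustering spectrum not fittable for this graph")
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        cpl=cpl,
        diameter=diam,
        avg_clustering=float(nx.average_clustering(g)) if n else 0.0,
        degree_fit=deg_fit,
        clustering_fit=clust_fit,
    )


def hubs(g: nx.Graph, top: int = 20) -> list[tuple[str, int]]:
    """Top-N nodes by degree; ties broken by identifier ascending."""
    if top > g.number_of_nodes():
        warnings.warn(
            f"hubs: top={top} exceeds node count {g.number_of_nodes()}; clipped",
            stacklevel=2,
        )
        top = g.number_of_nodes()
    ranked = sorted(g.degree, key=lambda nd: (-nd[1], nd[0]))
    return [(v, int(d)) for v, d in ranked[:top]]


def components_after_deletion(g: nx.Graph, v: str) -> tuple[int, float]:
    """Connected-component count after deleting ``v`` and its fold change.

    Isolated survivors count as components; the fold change is against the
    component count of the intact graph.
    """
    if v not in g:
        raise MissingProteinError(f"node {v!r} absent from the network")
    before = nx.number_connected_components(g)
    h = g.copy()
    h.remove_node(v)
    after = nx.number_connected_components(h)
    return after, after / before
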