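"""Typed kinase-interactome construction, topology and module extraction.

Networks are first-neighbor graphs: every interaction record with a hit
kinase at either end contributes an edge, pulling in the partner protein.
Edges carry one of four relation classes — (1) interacting protein,
(2) interacting phosphoprotein, (3) substrate, (4) substrate that is also an
interacting phosphoprotein. Graphs are undirected for topology; the
kinase->substrate orientation of substrate-class records is retained as an
edge attribute for display.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .exceptions import FitError, ValidationError
from .io import RELATION_CLASSES, RELATION_NAMES

logger = logging.getLogger(__name__)

#: Precedence when duplicate records disagree on a pair's relation class.
#: The classes are cumulative in information content: substrate-and-
#: interacting-phosphoprotein (4) > interacting phosphoprotein (2) >
#: substrate (3) > plain interaction (1).
RELATION_PRECEDENCE = {4: 3, 2: 2, 3: 1, 1: 0}


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    clustering_coefficient: float
    n_hit_kinases_included: int
    power_law_gamma: float | None = None
    gamma_fit_method: str | None = None


@dataclass
class PowerLawFit:
    """Degree-distribution power-law fit P(k) ~ k^-gamma for k >= xmin."""

    gamma: float
    xmin: int
    n_tail: int
    method: str
    gamma_continuous: float
    gamma_regression: float | None


def build_network(
    hit_kinases,
    interactions: pd.DataFrame,
) -> tuple[nx.Graph, list[str]]:
    """First-neighbor typed graph around a hit-kinase list.

    Keeps every interaction record with a hit kinase as source or target;
    partner proteins enter as non-hit nodes. Duplicate records for one
    unordered pair are merged keeping the most informative relation class
    (:data:`RELATION_PRECEDENCE`); conflicts are logged. Hit kinases absent
    from the table are returned as the unmapped report.

    Returns ``(graph, unmapped_hits)``. An empty hit list raises; an empty
    resulting graph is returned (with a log warning), not an error.
    """
    hits = {str(g).upper() for g in hit_kinases}
    if not hits:
        raise ValidationError("build_network: empty hit list")
    best: dict[tuple[str, str], int] = {}
    direction: dict[tuple[str, str], str] = {}
    for source, target, relation in interactions[
        ["source", "target", "relation"]
    ].itertuples(index=False):
        if source not in hits and target not in hits:
            continue
        code = RELATION_CLASSES[relation]
        key = (source, target) if source <= target else (target, source)
        prev = best.get(key)
        if prev is None or RELATION_PRECEDENCE[code] > RELATION_PRECEDENCE[prev]:
            if prev is not None and prev != code:
                logger.info(
                    "conflicting relation classes for %s-%s: kept %s over %s",
                    key[0], key[1], RELATION_NAMES[code], RELATION_NAMES[prev],
                )
            best[key] = code
            if code in (3, 4):
                direction[key] = f"{source}->{target}"
        elif prev != code:
            logger.info(
                "conflicting relation classes for %s-%s: kept %s over %s",
                key[0], key[1], RELATION_NAMES[prev], RELATION_NAMES[code],
            )
    graph = nx.Graph()
    for (u, v), code in sorted(best.items()):
        graph.add_edge(
            u,
            v,
            relation=code,
            relation_name=RELATION_NAMES[code],
            direction=direction.get((u, v), ""),
        )
    for node in graph.nodes:
        graph.nodes[node]["is_hit_kinase"] = node in hits
    unmapped = sorted(hits - set(graph.nodes))
    if graph.number_of_nodes() == 0:
        logger.warning("no interaction records touch the hit list; empty graph")
    return graph, unmapped


def degree_stats(graph: nx.Graph) -> tuple[dict[int, int], TopologySummary]:
    """Degree histogram plus the topology summary (gamma left unfit)."""
    n = graph.number_of_nodes()
    if n == 0:
        return {}, TopologySummary(0, 0, 0, 0.0, 0.0, 0)
    degrees = [d for _, d in graph.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    summary = TopologySummary(
        n_nodes=n,
        n_edges=graph.number_of_edges(),
        n_components=nx.number_connected_components(graph),
        mean_degree=2 * graph.number_of_edges() / n,
        clustering_coefficient=nx.average_clustering(graph) if n > 1 else 0.0,
        n_hit_kinases_included=sum(
            1 for _, hit in graph.nodes(data="is_hit_kinase") if hit
        ),
    )
    return dict(sorted(hist.items())), summary


def fit_power_law(degrees, xmin: int | None = None, scan_xmin: bool = True) -> PowerLawFit:
    """Fit P(k) ~ k^-gamma to a degree sequence by discrete maximum likelihood.

    The primary estimate maximizes the zeta-normalized discrete power-law
    likelihood over the tail ``k >= xmin`` (Hurwitz-zeta normalization); the
    continuous ML approximation ``1 + n / sum ln(k/(xmin-0.5))`` and the
    log-log histogram regression slope are reported as diagnostics. Unless
    ``xmin`` is given, it is chosen by scanning candidate cutoffs and
    minimizing the tail Kolmogorov-Smirnov distance between data and fitted
    model — real degree sequences are power laws only above a knee, and for
    a clean power-law sample the scan settles on the minimum degree anyway.
    ``scan_xmin=False`` fixes xmin at the minimum observed positive degree.
    """
    ks = np.asarray(degrees, dtype=float)
    ks = ks[np.isfinite(ks)]
    ks = ks[ks >= 1].astype(int)
    if len(ks) == 0:
        raise FitError("no positive degrees to fit")
    if scan_xmin and xmin is None:
        candidates = [x for x in sorted(set(ks)) if (ks >= x).sum() >= 10]
        fits = [(_ks_distance(ks[ks >= x], _mle_gamma(ks[ks >= x], x), x), x) for x in candidates]
        if not fits:
            raise FitError("fewer than 10 degrees above every candidate xmin")
        xmin = min(fits)[1]
    if xmin is None:
        xmin = int(ks.min())
    tail = ks[ks >= xmin]
    if len(tail) < 10:
        raise FitError(f"need >= 10 degrees with degree >= xmin ({xmin})")
    if tail.min() == tail.max():
        raise FitError("all degrees equal; a power-law exponent is undefined")
    gamma = _mle_gamma(tail, xmin)
    gamma_cont = 1.0 + len(tail) / float(np.sum(np.log(tail / (xmin - 0.5))))
    gamma_reg = _loglog_slope(tail)
    return PowerLawFit(
        gamma=gamma,
        xmin=int(xmin),
        n_tail=len(tail),
        method="discrete_mle",
        gamma_continuous=gamma_cont,
        gamma_regression=gamma_reg,
    )


def _mle_gamma(tail: np.ndarray, xmin: int) -> float:
    mean_log = float(np.mean(np.log(tail)))

    def nll(g: float) -> float:
        return math.log(zeta(g, xmin)) + g * mean_log

    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, gamma: float, xmin: int) -> float:
    kmax = int(tail.max())
    support = np.arange(xmin, kmax + 1)
    pmf = support ** (-gamma) / zeta(gamma, xmin)
    model_cdf = np.cumsum(pmf)
    emp_cdf = np.searchsorted(np.sort(tail), support, side="right") / len(tail)
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def _loglog_slope(tail: np.ndarray) -> float | None:
    vals, counts = np.unique(tail, return_counts=True)
    if len(vals) < 3:
        return None
    slope = np.polyfit(np.log(vals), np.log(counts), 1)[0]
    return float(-slope)


def summarize_topology(graph: nx.Graph, fit_gamma: bool = True) -> TopologySummary:
    """Topology summary with the power-law exponent filled in when fittable."""
    _, summary = degree_stats(graph)
    if fit_gamma and graph.number_of_nodes() >= 10:
        try:
            fit = fit_power_law([d for _, d in graph.degree()])
            summary.power_law_gamma = fit.gamma
            summary.gamma_fit_method = fit.method
        except FitError:
            pass
    return summary


def extract_module(graph: nx.Graph, seeds, radius: int = 1) -> nx.Graph:
    """Induced subgraph on all nodes within ``radius`` hops of any seed."""
    seed_list = [str(s).upper() for s in seeds]
    missing = sorted(s for s in seed_list if s not in graph)
    if missing:
        raise ValidationError(f"seeds absent from graph: {', '.join(missing)}")
    keep: set[str] = set()
    for seed in seed_list:
        keep.update(nx.single_source_shortest_path_length(graph, seed, cutoff=radius))
    return graph.subgraph(keep).copy()


def shared_neighbor_modules(
    graph: nx.Graph, min_shared: int = 2
) -> list[tuple[tuple[str, str], list[str]]]:
    """Hit-kinase pairs sharing at least ``min_shared`` non-hit neighbors.

    Operationalizes visual module spotting: two hit kinases jointly wired to
    a common set of partners form a candidate module. Pairs are ranked by
    shared-neighbor count (descending), ties broken alphabetically. Returns
    ``[((kinase_a, kinase_b), sorted shared neighbors), ...]``.
    """
    hit_nodes = sorted(n for n, h in graph.nodes(data="is_hit_kinase") if h)
    results = []
    for a, b in itertools.combinations(hit_nodes, 2):
        shared = {
            n
            for n in set(graph.neighbors(a)) & set(graph.neighbors(b))
            if not graph.nodes[n].get("is_hit_kinase", False)
        }
        if len(shared) >= min_shared:
            results.append(((a, b), sorted(shared)))
    results.sort(key=lambda item: (-len(item[1]), item[0]))
    return results
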