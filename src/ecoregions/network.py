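"""Lagged functional-network inference among domains.

Each domain A carries a signal X_A(t): the cosine-latitude-weighted sum of
its cell anomaly series.  For every unordered pair (A, B) the Pearson
cross-correlation r_AB(tau) is computed over tau in [-tau_max, tau_max] and
each lag is tested for significance with the autocorrelation-corrected
(Bartlett) variance of the null, so serially correlated signals do not
inflate the edge count.  A pair is linked if at least one lag is significant;
the link is directed A->B (B->A) when the significant lag set is strictly
positive (negative) and undirected otherwise.  The edge weight is the sample
covariance of the aligned signals at the |r|-maximizing significant lag, and
a domain's strength is the sum of |weight| over its incident edges.

No correction for testing 2*tau_max+1 lags per pair is applied by default
(``lag_correction="none"``); with ``lag_correction="sidak"`` the per-lag
level is deflated so the per-pair false-edge probability equals ``level``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .grid import GriddedField
from .domains import Domain, DomainSet

__all__ = [
    "Edge", "FunctionalNetwork",
    "domain_signal", "domain_signals", "lagged_correlation", "sample_autocorr",
    "bartlett_variance", "bartlett_significance", "direction_from_lags",
    "infer_network", "save_network", "load_network",
]

UNDIRECTED = "undirected"


@dataclass
class Edge:
    A: object
    B: object
    lag_set: tuple          # significant lags, ascending
    tau_star: int           # |r|-maximizing significant lag
    r: float                # correlation at tau_star
    w: float                # covariance at tau_star
    direction: str          # "undirected" | "A->B" | "B->A"


@dataclass
class FunctionalNetwork:
    nodes: dict             # id -> strength
    edges: list
    level: float
    tau_max: int

    def strength(self, node) -> float:
        return self.nodes[node]

    def edge_between(self, a, b) -> Edge | None:
        for e in self.edges:
            if {e.A, e.B} == {a, b}:
                return e
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"A": e.A, "B": e.B, "direction": e.direction, "tau_star": e.tau_star,
                 "r": e.r, "w": e.w, "lag_set": " ".join(map(str, e.lag_set))}
                for e in self.edges
            ],
            columns=["A", "B", "direction", "tau_star", "r", "w", "lag_set"],
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, s in self.nodes.items():
            g.add_node(node, strength=float(s))
        for e in self.edges:
            g.add_edge(e.A, e.B, direction=e.direction, tau_star=int(e.tau_star),
                       r=float(e.r), w=float(e.w),
                       lag_set=" ".join(map(str, e.lag_set)))
        return g


def domain_signal(domain, anoms: GriddedField) -> np.ndarray:
    """X_A(t) = sum over cells of x_i(t) * cos(latitude_i), latitude in radians."""
    cells = domain.cells if isinstance(domain, Domain) else list(domain)
    if not cells:
        raise ValueError("cannot build a signal for an empty domain")
    ii = np.array([c[0] for c in cells])
    jj = np.array([c[1] for c in cells])
    weights = np.cos(np.radians(anoms.lat[ii]))
    return anoms.values[:, ii, jj] @ weights


def domain_signals(ds: DomainSet, anoms: GriddedField) -> dict:
    return {d.id: domain_signal(d, anoms) for d in ds.domains}


def lagged_correlation(xa: np.ndarray, xb: np.ndarray, tau_max: int) -> np.ndarray:
    """r_AB(tau) = corr(xa(t), xb(t + tau)) for tau in [-tau_max, tau_max].

    Each lag uses the overlapping T - |tau| points.  Returns an array of
    length 2*tau_max + 1 indexed by tau + tau_max; lags with zero-variance
    overlap are NaN.  Antisymmetry holds: r_AB(tau) = r_BA(-tau).
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    T = len(xa)
    if len(xb) != T:
        raise ValueError("series must have equal length")
    if T <= tau_max + 3:
        raise ValueError(f"need T > tau_max + 3 (T={T}, tau_max={tau_max})")
    out = np.full(2 * tau_max + 1, np.nan)
    for tau in range(-tau_max, tau_max + 1):
        if tau >= 0:
            a, b = xa[: T - tau], xb[tau:]
        else:
            a, b = xa[-tau:], xb[: T + tau]
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na > 0 and nb > 0:
            out[tau + tau_max] = float(a @ b / (na * nb))
    return out


def sample_autocorr(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased sample autocorrelation rho(0..nlags) via FFT."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    T = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: nlags + 1] / T
    if acov[0] <= 0:
        return np.zeros(nlags + 1)
    return acov / acov[0]


def bartlett_variance(
    xa: np.ndarray, xb: np.ndarray, tau: int, nlags: int | None = None
) -> float:
    """Null variance of r_AB(tau) for independent autocorrelated series.

    var = (1 / (T - |tau|)) * sum_k rho_A(k) rho_B(k), the sum running over
    k = -K..K with sample autocorrelations truncated at K = min(T/3, 50).
    A non-positive estimate is clamped to the white-noise floor 1/(T - |tau|).
    """
    T = len(xa)
    n = T - abs(tau)
    if nlags is None:
        nlags = min(T // 3, 50)
    ra = sample_autocorr(xa, nlags)
    rb = sample_autocorr(xb, nlags)
    s = 1.0 + 2.0 * float(ra[1:] @ rb[1:])
    if s <= 0:
        s = 1.0  # white-noise floor
    return s / n


def bartlett_significance(
    xa: np.ndarray,
    xb: np.ndarray,
    tau: int,
    level: float,
    dist: str = "t",
    nlags: int | None = None,
    r: float | None = None,
) -> bool:
    """Two-sided significance of r_AB(tau) against the Bartlett null variance.

    The statistic r / sqrt(var) is referred to a t distribution with T-2
    degrees of freedom (``dist="t"``, the default) or to a standard normal.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    T = len(xa)
    if r is None:
        tau_max = abs(tau)
        r = lagged_correlation(xa, xb, max(tau_max, 1))[tau + max(tau_max, 1)]
    if not np.isfinite(r):
        return False
    var = bartlett_variance(xa, xb, tau, nlags)
    stat = abs(r) / np.sqrt(var)
    if dist == "t":
        crit = stats.t.ppf(1 - level / 2, T - 2)
    elif dist == "normal":
        crit = stats.norm.ppf(1 - level / 2)
    else:
        raise ValueError("dist must be 't' or 'normal'")
    return bool(stat > crit)


def direction_from_lags(lag_set) -> str:
    """Directionality rule: strictly positive lags mean A leads B (A->B),
    strictly negative mean B->A; any set containing 0 (or mixed signs) is
    undirected."""
    lags = sorted(lag_set)
    if not lags:
        raise ValueError("empty lag set")
    if all(l > 0 for l in lags):
        return "A->B"
    if all(l < 0 for l in lags):
        return "B->A"
    return UNDIRECTED


def _aligned(xa, xb, tau):
    T = len(xa)
    if tau >= 0:
        return xa[: T - tau], xb[tau:]
    return xa[-tau:], xb[: T + tau]


def infer_network(
    signals: dict,
    tau_max: int = 12,
    level: float = 0.03,
    dist: str = "t",
    lag_correction: str = "none",
    nlags: int | None = None,
) -> FunctionalNetwork:
    """Build the weighted, possibly directed network over domain signals.

    Parameters
    ----------
    signals : mapping id -> 1-D array
    tau_max : lag range in months (default 12)
    level : two-sided significance level per pair (default 0.03)
    lag_correction : "none" tests each lag at `level`; "sidak" deflates the
        per-lag level to 1-(1-level)^(1/(2 tau_max+1)).
    """
    ids = sorted(signals)
    if len(ids) < 2:
        return FunctionalNetwork(
            nodes={i: 0.0 for i in ids}, edges=[], level=level, tau_max=tau_max
        )
    n_lags = 2 * tau_max + 1
    if lag_correction == "sidak":
        eff_level = 1.0 - (1.0 - level) ** (1.0 / n_lags)
    elif lag_correction == "none":
        eff_level = level
    else:
        raise ValueError("lag_correction must be 'none' or 'sidak'")

    edges = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            A, B = ids[ai], ids[bi]
            xa, xb = np.asarray(signals[A], float), np.asarray(signals[B], float)
            r = lagged_correlation(xa, xb, tau_max)
            sig_lags = [
                tau for tau in range(-tau_max, tau_max + 1)
                if np.isfinite(r[tau + tau_max])
                and bartlett_significance(
                    xa, xb, tau, eff_level, dist=dist, nlags=nlags,
                    r=r[tau + tau_max],
                )
            ]
            if not sig_lags:
                continue
            tau_star = max(
                sig_lags, key=lambda t: (abs(r[t + tau_max]), -abs(t), t)
            )
            a, b = _aligned(xa, xb, tau_star)
            w = float(np.cov(a, b, ddof=1)[0, 1])
            edges.append(Edge(
                A=A, B=B, lag_set=tuple(sorted(sig_lags)), tau_star=tau_star,
                r=float(r[tau_star + tau_max]), w=w,
                direction=direction_from_lags(sig_lags),
            ))

    strengths = {i: 0.0 for i in ids}
    for e in edges:
        strengths[e.A] += abs(e.w)
        strengths[e.B] += abs(e.w)
    return FunctionalNetwork(nodes=strengths, edges=edges, level=level, tau_max=tau_max)


# -- serialization -----------------------------------------------------------

def save_network(net: FunctionalNetwork, path, fmt: str = "json") -> None:
    """Write a network as JSON, CSV edge list, or GraphML."""
    if fmt == "json":
        payload = {
            "level": net.level, "tau_max": net.tau_max,
            "nodes": {str(k): v for k, v in net.nodes.items()},
            "edges": [
                {"A": e.A, "B": e.B, "lag_set": list(e.lag_set),
                 "tau_star": e.tau_star, "r": e.r, "w": e.w,
                 "direction": e.direction}
                for e in net.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    elif fmt == "csv":
        net.to_dataframe().to_csv(path, index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError("fmt must be 'json', 'csv' or 'graphml'")


def load_network(path) -> FunctionalNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    return FunctionalNetwork(
        nodes={int(k): v for k, v in payload["nodes"].items()},
        edges=[
            Edge(A=e["A"], B=e["B"], lag_set=tuple(e["lag_set"]),
                 tau_star=e["tau_star"], r=e["r"], w=e["w"],
                 direction=e["direction"])
            for e in payload["edges"]
        ],
        level=payload["level"], tau_max=payload["tau_max"],
    )
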