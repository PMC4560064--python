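"""Enumerate, score, filter and rank OTU-triplets; assemble the signed network.

Every ordered triple of distinct OTUs ``(m, c, t)`` — cooperator, competitor,
target — is scored against the NRO model surface.  Triplets passing the
``L_d`` / ``D`` thresholds are ranked by the integrated score ``I`` and each
retained triplet contributes two directed signed edges to the regulatory
network: a cooperative edge ``m -> t`` and a competitive edge ``c -| t``.
The cooperator-competitor pair itself contributes no edge.

Both ``(m, c, t)`` and ``(c, m, t)`` are enumerated: the surface is
antisymmetric in its two regulators, so the two orderings fit differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nro_core import TripletScores, ld_transform

__all__ = [
    "COOPERATIVE",
    "COMPETITIVE",
    "ScoredTriplet",
    "ThresholdConfig",
    "RegulatoryNetwork",
    "SignConflictError",
    "score_arrays",
    "scan_triplets",
    "filter_triplets",
    "rank_triplets",
    "build_network",
]

COOPERATIVE = "cooperative"
COMPETITIVE = "competitive"

# lack-of-fit denominators below this count as degenerate (a constant target
# series leaves only rounding residue ~1e-33; real SRP targets give O(0.1))
_DEN_TINY = 1e-15


@dataclass(frozen=True)
class ScoredTriplet:
    """An ordered OTU-triplet (cooperator m, competitor c, target t) with scores."""

    m: int
    c: int
    t: int
    scores: TripletScores

    def __post_init__(self):
        if len({self.m, self.c, self.t}) != 3:
            raise ValueError("triplet indices must be distinct")


@dataclass(frozen=True)
class ThresholdConfig:
    """Filter thresholds: keep triplets with ``0 <= L_d <= ld_max`` and ``D < d_max``."""

    ld_max: float = 3.8
    d_max: float = 0.8
    top_k: int | None = None

    def __post_init__(self):
        if self.ld_max < 0 or self.d_max < 0:
            raise ValueError("thresholds must be non-negative")


class SignConflictError(ValueError):
    """The same ordered OTU pair is implied both cooperative and competitive."""


@dataclass
class RegulatoryNetwork:
    """Signed directed microbial network.

    ``edges`` maps ``(source, target, sign)`` — sign in {"cooperative",
    "competitive"} — to the list of supporting triplets (provenance).  An
    ordered pair never carries both signs.
    """

    nodes: list = field(default_factory=list)
    edges: dict = field(default_factory=dict)

    def add_edge(self, source, target, sign, triplet=None):
        if source == target:
            raise ValueError("self-edges are not allowed")
        if sign not in (COOPERATIVE, COMPETITIVE):
            raise ValueError(f"unknown sign {sign!r}")
        other = COMPETITIVE if sign == COOPERATIVE else COOPERATIVE
        if (source, target, other) in self.edges:
            raise SignConflictError(
                f"edge {source}->{target} already carries sign {other!r}; "
                f"conflicting support: {self.edges[(source, target, other)]} "
                f"vs {triplet}"
            )
        for node in (source, target):
            if node not in self.nodes:
                self.nodes.append(node)
        support = self.edges.setdefault((source, target, sign), [])
        if triplet is not None:
            support.append(triplet)

    def edge_set(self):
        """The set of (source, target, sign) keys."""
        return set(self.edges)

    def best_integrated_score(self, key):
        support = self.edges[key]
        if not support:
            return float("nan")
        return min(trip.scores.I for trip in support)

    def to_networkx(self):
        """Export as a ``networkx.DiGraph`` with ``sign`` edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (src, tgt, sign), support in self.edges.items():
            g.add_edge(src, tgt, sign=sign, n_supporting=len(support))
        return g

    def __len__(self):
        return len(self.edges)


def score_arrays(srp: np.ndarray):
    """Score all ordered distinct triplets of an SRP matrix at once.

    Parameters
    ----------
    srp : ndarray, shape (n_otus, k)
        Standardized relative proportions, values in [0, 1], no constant row.

    Returns
    -------
    dict of ndarray, each shape (n, n, n)
        Keys ``"L"``, ``"D"``, ``"I"``, ``"Ld"``, indexed ``[m, c, t]``;
        entries with non-distinct indices are NaN.

    Notes
    -----
    This is the array path behind :func:`scan_triplets` and the benchmark:
    the surface is evaluated for every regulator pair, residuals against every
    target give ``L``, and the leave-one-out values ``L_(n)`` come from
    closed-form downdates of the residual and deviation sums, with the target
    mean recomputed on the k-1 remaining points.
    """
    P = np.asarray(srp, dtype=float)
    if P.ndim != 2:
        raise ValueError("srp must be 2-D (n_otus x n_timepoints)")
    n, k = P.shape
    if n < 3 or k < 3:
        raise ValueError("need at least 3 OTUs and 3 time points")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("SRP values must lie in [0, 1]")

    t_ = np.tanh(1.1 * P)
    pm, pc = P[:, None, :], P[None, :, :]
    tm, tc = t_[:, None, :], t_[None, :, :]
    surf = tm - tc + 0.5
    surf = np.where((pm < 0.5) & (pc > 0.5), 2.0 * tm * (1.0 - tc), surf)
    surf = np.where((pm > 0.5) & (pc < 0.5), 1.0 - 2.0 * (1.0 - tm) * tc, surf)
    np.clip(surf, 0.0, 1.0, out=surf)  # (m, c, time)

    resid = P[None, None, :, :] - surf[:, :, None, :]  # (m, c, t, time)
    resid2 = resid**2
    num = resid2.sum(axis=-1)  # (m, c, t)

    if np.any(np.ptp(P, axis=1) == 0.0):
        bad = int(np.argmax(np.ptp(P, axis=1) == 0.0))
        raise ValueError(f"degenerate target: OTU row {bad} is constant")
    mean_t = P.mean(axis=1)
    den = ((P - mean_t[:, None]) ** 2).sum(axis=1)  # (t,)
    L = num / den[None, None, :]

    # leave-one-out: numerator minus the dropped residual; denominator of the
    # k-1 remaining target points about their own mean.
    s1, s2 = P.sum(axis=1), (P**2).sum(axis=1)
    den_loo = (s2[:, None] - P**2) - (s1[:, None] - P) ** 2 / (k - 1)  # (t, time)
    num_loo = num[..., None] - resid2  # (m, c, t, time)
    with np.errstate(divide="ignore", invalid="ignore"):
        L_loo = num_loo / den_loo[None, None, :, :]
        L_loo = np.where(den_loo[None, None, :, :] <= _DEN_TINY, np.nan, L_loo)
        r = L_loo / L[..., None]
        terms = np.abs(r * np.log10(r))
    terms = np.where(r == 0.0, 0.0, terms)
    D = np.nansum(terms, axis=-1)
    D = np.where(L == 0.0, 0.0, D)

    I = L * (1.0 + D)
    Ld = ld_transform(L)

    idx = np.arange(n)
    distinct = (
        (idx[:, None, None] != idx[None, :, None])
        & (idx[:, None, None] != idx[None, None, :])
        & (idx[None, :, None] != idx[None, None, :])
    )
    nanfill = np.where(distinct, 0.0, np.nan)
    return {
        "L": L + nanfill,
        "D": D + nanfill,
        "I": I + nanfill,
        "Ld": Ld + nanfill,
    }


def scan_triplets(srp: np.ndarray) -> list[ScoredTriplet]:
    """Score every ordered triple of distinct OTUs: ``n*(n-1)*(n-2)`` triplets."""
    arrs = score_arrays(srp)
    n = arrs["L"].shape[0]
    out = []
    for m in range(n):
        for c in range(n):
            for t in range(n):
                if m == c or m == t or c == t:
                    continue
                out.append(
                    ScoredTriplet(
                        m,
                        c,
                        t,
                        TripletScores(
                            L=float(arrs["L"][m, c, t]),
                            D=float(arrs["D"][m, c, t]),
                            I=float(arrs["I"][m, c, t]),
                            L_d=float(arrs["Ld"][m, c, t]),
                        ),
                    )
                )
    return out


def filter_triplets(triplets, cfg: ThresholdConfig):
    """Keep triplets with ``0 <= L_d <= cfg.ld_max`` and ``D < cfg.d_max``."""
    return [
        trip
        for trip in triplets
        if 0.0 <= trip.scores.L_d <= cfg.ld_max and trip.scores.D < cfg.d_max
    ]


def rank_triplets(triplets):
    """Sort ascending by I; ties by L, then by (m, c, t), for determinism."""
    return sorted(triplets, key=lambda tr: (tr.scores.I, tr.scores.L, tr.m, tr.c, tr.t))


def build_network(
    triplets,
    top_k: int | None = None,
    otu_ids=None,
    conflict: str = "error",
) -> RegulatoryNetwork:
    """Assemble the signed directed network from filtered, ranked triplets.

    Each retained triplet (up to ``top_k``) adds a cooperative edge m->t and a
    competitive edge c->t; duplicate edges merge, recording all supporting
    triplets.  A pair implied with both signs raises
    :class:`SignConflictError` when ``conflict="error"``; with
    ``conflict="permissive"`` the sign supported by the lower-I triplet wins.
    """
    if conflict not in ("error", "permissive"):
        raise ValueError("conflict must be 'error' or 'permissive'")
    chosen = list(triplets if top_k is None else triplets[:top_k])

    def label(i):
        return otu_ids[i] if otu_ids is not None else i

    if conflict == "permissive":
        # best (lowest-I) support decides the sign of a contested pair;
        # exact I ties go to the cooperative sign
        best = {}
        for trip in chosen:
            for src, sign in ((trip.m, COOPERATIVE), (trip.c, COMPETITIVE)):
                key = (src, trip.t)
                rank = (trip.scores.I, 0 if sign == COOPERATIVE else 1)
                if key not in best or rank < best[key][1]:
                    best[key] = (sign, rank)

    net = RegulatoryNetwork()
    for trip in chosen:
        for src, sign in ((trip.m, COOPERATIVE), (trip.c, COMPETITIVE)):
            if conflict == "permissive" and best[(src, trip.t)][0] != sign:
                continue
            net.add_edge(label(src), label(trip.t), sign, triplet=trip)
    return net
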