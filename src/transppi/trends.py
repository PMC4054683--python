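"""Topological trends across association significance thresholds.

Source-target pairs are sorted by ascending association p-value; every
prefix of that list (each new on-network pair defines a threshold) yields
cumulative averages of three topological properties: source-target network
distance, source degree, and target degree.  Each cumulative-average curve
is summarized by Spearman's rank correlation against the prefix threshold
(-log10 p of the last pair included), and that correlation is assessed
against permuted source-target pair sets that reuse the real p-value
ordering but random network positions.

The diagnostic signature of true trans signal diluted by false positives:
distance rises (r < 0 against -log10 p) and target degree falls (r > 0) as
the threshold loosens.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import PermutationNull, SourceTargetPair, TrendProfile
from .errors import InsufficientDataError, InvalidParameterError
from .network import DistanceMatrix, PPINetwork, degree
from .permutation import derive_seed, sample_network_pairs, sample_random_pairs

__all__ = [
    "PROPERTIES", "cumulative_property_profile", "permuted_trend_distribution",
    "empirical_p", "trend_significance",
]

PROPERTIES = ("distance", "source_degree", "target_degree")

#: alternative direction per property for the planted/expected trend:
#: distance should fall with significance (r < 0), degrees should rise (r > 0).
TREND_DIRECTION = {"distance": "less", "source_degree": "greater",
                   "target_degree": "greater"}

_P_FLOOR = 1e-300  # guards -log10 against numerically zero p-values


def _on_network(pairs: Sequence[SourceTargetPair], distances: DistanceMatrix,
                p_max: float) -> list[SourceTargetPair]:
    kept = [r for r in pairs
            if r.assoc.p <= p_max
            and r.source_gene in distances and r.target_gene in distances]
    kept.sort(key=lambda r: (r.assoc.p, r.esnp_id, r.target_gene))
    return kept


def _profile_from_arrays(thresholds: np.ndarray,
                         props: Mapping[str, np.ndarray]) -> TrendProfile:
    cum, rs, degen = {}, {}, {}
    n = thresholds.size
    denom = np.arange(1, n + 1, dtype=float)
    for name, values in props.items():
        means = np.cumsum(values, dtype=float) / denom
        cum[name] = means
        if np.ptp(means) == 0 or np.ptp(thresholds) == 0:
            rs[name] = 0.0
            degen[name] = True
        else:
            rs[name] = float(stats.spearmanr(thresholds, means).statistic)
            degen[name] = False
    return TrendProfile(thresholds=thresholds, n_pairs=np.arange(1, n + 1),
                        cumulative_means=cum, spearman_r=rs, degenerate=degen)


def cumulative_property_profile(pairs: Sequence[SourceTargetPair],
                                distances: DistanceMatrix,
                                network: PPINetwork,
                                p_max: float = 1e-6) -> TrendProfile:
    """Cumulative topological averages over significance prefixes.

    Only on-network pairs with p <= ``p_max`` enter; at least two are
    required to define a trend.  A zero-variance curve (all prefix means
    equal) gets r reported as 0 with its ``degenerate`` flag set.
    """
    kept = _on_network(pairs, distances, p_max)
    if len(kept) < 2:
        raise InsufficientDataError(
            f"{len(kept)} on-network pair(s) at p <= {p_max}; trend undefined")
    thresholds = np.array([-np.log10(max(r.assoc.p, _P_FLOOR)) for r in kept])
    props = {
        "distance": np.array([distances.d(r.source_gene, r.target_gene)
                              for r in kept], dtype=float),
        "source_degree": np.array([degree(network, r.source_gene)
                                   for r in kept], dtype=float),
        "target_degree": np.array([degree(network, r.target_gene)
                                   for r in kept], dtype=float),
    }
    return _profile_from_arrays(thresholds, props)


def permuted_trend_distribution(real_pairs: Sequence[SourceTargetPair],
                                network: PPINetwork,
                                distances: DistanceMatrix,
                                n_perm: int = 100_000,
                                seed: int = 0,
                                p_max: float = 1e-6,
                                scheme: str = "network_uniform",
                                ) -> dict[str, PermutationNull]:
    """Null distribution of the trend correlation for each property.

    Each permutation draws as many source-target node pairs as the real
    on-network list, assigns them the real pairs' p-value ordering, and
    computes the same prefix-wise Spearman correlation.  ``scheme`` selects
    uniform node pairs (default) or edge switching over the real source and
    target multisets.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be positive")
    kept = _on_network(real_pairs, distances, p_max)
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 on-network pairs; no trend to permute")
    thresholds = np.array([-np.log10(max(r.assoc.p, _P_FLOOR)) for r in kept])
    n = len(kept)
    if scheme == "edge_switching":
        sources = [r.source_gene for r in kept]
        targets = [r.target_gene for r in kept]
    elif scheme != "network_uniform":
        raise InvalidParameterError(f"unknown scheme {scheme!r}")

    node_list = distances.nodes
    node_pos = {v: i for i, v in enumerate(node_list)}
    deg = np.array([degree(network, v) if network.has_node(v) else 0
                    for v in node_list], dtype=float)

    out = {name: np.empty(n_perm) for name in PROPERTIES}
    rank_thr = stats.rankdata(thresholds)
    for k in range(n_perm):
        sub = derive_seed(seed, f"trend_{scheme}", k)
        if scheme == "network_uniform":
            pair_set = sample_network_pairs(network, n, sub).pairs
        else:
            pair_set = sample_random_pairs(sources, targets, n, sub).pairs
        si = np.array([node_pos[s] for (s, _) in pair_set])
        ti = np.array([node_pos[t] for (_, t) in pair_set])
        denom = np.arange(1, n + 1, dtype=float)
        for name, values in (
            ("distance", distances.matrix[si, ti].astype(float)),
            ("source_degree", deg[si]),
            ("target_degree", deg[ti]),
        ):
            means = np.cumsum(values) / denom
            if np.ptp(means) == 0 or np.ptp(thresholds) == 0:
                out[name][k] = 0.0
            else:
                rm = stats.rankdata(means)
                c = np.corrcoef(rank_thr, rm)[0, 1]
                out[name][k] = c
    return {name: PermutationNull(statistics=vals, seed=int(seed))
            for name, vals in out.items()}


def empirical_p(real_r: float, null: PermutationNull, direction: str) -> float:
    """Fraction of permuted statistics strictly beyond the real one.

    ``direction='greater'`` counts permuted > real, ``'less'`` counts
    permuted < real.  The count is strict and the plain count/n_perm ratio
    is returned (it can be exactly 0); a pseudocount (r+1)/(n+1) variant is
    available via :func:`empirical_p_pseudocount`.
    """
    if direction not in ("greater", "less"):
        raise InvalidParameterError("direction must be 'greater' or 'less'")
    s = null.statistics
    count = int((s > real_r).sum() if direction == "greater" else (s < real_r).sum())
    return count / null.n_perm


def empirical_p_pseudocount(real_r: float, null: PermutationNull, direction: str) -> float:
    """(count + 1) / (n_perm + 1) variant of :func:`empirical_p`."""
    if direction not in ("greater", "less"):
        raise InvalidParameterError("direction must be 'greater' or 'less'")
    s = null.statistics
    count = int((s > real_r).sum() if direction == "greater" else (s < real_r).sum())
    return (count + 1) / (null.n_perm + 1)


def trend_significance(profile: TrendProfile,
                       nulls: Mapping[str, PermutationNull]) -> dict[str, dict[str, float]]:
    """Empirical significance of each property's trend correlation.

    Reports the direction-consistent p (distance tested toward smaller r,
    degrees toward larger r) alongside the raw 'permuted r > real r'
    convention, so both readings are on record.
    """
    out: dict[str, dict[str, float]] = {}
    for name in PROPERTIES:
        real_r = profile.spearman_r[name]
        null = nulls[name]
        out[name] = {
            "r": real_r,
            "empirical_p": empirical_p(real_r, null, TREND_DIRECTION[name]),
            "empirical_p_greater": empirical_p(real_r, null, "greater"),
        }
    return out
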