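"""Random-pair and random-set constructions for permutation nulls.

Two sampling schemes are used throughout:

* *edge switching* — a random pair takes its source from the multiset of
  observed sources and, independently, its target from the multiset of
  observed targets.  This preserves both marginal frequencies exactly in
  expectation while destroying the source-target matching.
* *network uniform* — unordered node pairs drawn uniformly from the graph's
  node set, used where the question is about arbitrary network positions
  rather than the observed association lists.

Each operation derives an independent sub-seed from (master seed, operation
label, replicate index) so that streams never collide and every draw is
reproducible.
"""

from __future__ import annotations

import zlib
from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import PermutationNull, RandomPairSet
from .errors import FeasibilityError, InvalidParameterError
from .network import PathRecord, PPINetwork

__all__ = [
    "derive_seed", "sample_random_pairs", "sample_network_pairs",
    "sample_permuted_tf_sets", "tf_multiplicity_test", "sample_length_matched_paths",
]


def derive_seed(master: int, label: str, index: int = 0) -> int:
    """Stable sub-seed for (master seed, operation label, replicate index)."""
    ss = np.random.SeedSequence(
        [int(master) & 0x7FFFFFFF, zlib.crc32(label.encode("utf8")), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def sample_random_pairs(real_sources: Sequence[str], real_targets: Sequence[str],
                        n: int, seed: int, unique: bool = False) -> RandomPairSet:
    """Edge-switching pairs: source and target drawn from the observed multisets.

    With ``unique=True``, duplicate (source, target) pairs and self-pairs are
    rejected and resampled; a :class:`FeasibilityError` is raised when fewer
    than ``n`` distinct valid combinations exist.
    """
    if not real_sources or not real_targets:
        raise InvalidParameterError("source and target multisets must be non-empty")
    if n < 1:
        raise InvalidParameterError("n must be positive")
    sources = list(real_sources)
    targets = list(real_targets)
    rng = np.random.default_rng(seed)
    if unique:
        distinct = {(s, t) for s in set(sources) for t in set(targets) if s != t}
        if len(distinct) < n:
            raise FeasibilityError(
                f"only {len(distinct)} distinct source!=target combinations, need {n}")
        chosen: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        while len(chosen) < n:
            s = sources[rng.integers(len(sources))]
            t = targets[rng.integers(len(targets))]
            if s == t or (s, t) in seen:
                continue
            seen.add((s, t))
            chosen.append((s, t))
    else:
        si = rng.integers(len(sources), size=n)
        ti = rng.integers(len(targets), size=n)
        chosen = [(sources[i], targets[j]) for i, j in zip(si, ti)]
    return RandomPairSet(pairs=tuple(chosen), scheme="edge_switching", seed=int(seed))


def sample_network_pairs(network: PPINetwork, n: int, seed: int) -> RandomPairSet:
    """``n`` unique unordered node pairs uniform over the network's nodes."""
    nodes = network.nodes()
    m = len(nodes)
    if m < 2:
        raise InvalidParameterError("network needs at least 2 nodes")
    n_possible = m * (m - 1) // 2
    if n > n_possible:
        raise FeasibilityError(f"requested {n} unique pairs but only {n_possible} exist")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[int, int]] = set()
    while len(chosen) < n:
        i = int(rng.integers(m))
        j = int(rng.integers(m))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        chosen.append((nodes[key[0]], nodes[key[1]]))
    return RandomPairSet(pairs=tuple(chosen), scheme="network_uniform", seed=int(seed))


def sample_permuted_tf_sets(real_tf_pairs: Sequence[tuple[str, str]],
                            n_sets: int = 1000, seed: int = 0) -> list[RandomPairSet]:
    """Permuted TF pair sets, each the size of the real list, by edge switching."""
    if not real_tf_pairs:
        raise InvalidParameterError("real TF pair list is empty")
    sources = [s for (s, _) in real_tf_pairs]
    targets = [t for (_, t) in real_tf_pairs]
    return [
        sample_random_pairs(sources, targets, len(real_tf_pairs),
                            seed=derive_seed(seed, "tf_sets", k))
        for k in range(n_sets)
    ]


def _multi_target_count(pairs: Sequence[tuple[str, str]]) -> tuple[int, list[int]]:
    per_source: dict[str, set[str]] = {}
    for (s, t) in pairs:
        per_source.setdefault(s, set()).add(t)
    counts = sorted(len(v) for v in per_source.values())
    return sum(c >= 2 for c in counts), counts


def tf_multiplicity_test(real_tf_pairs: Sequence[tuple[str, str]],
                         permuted_sets: Sequence[RandomPairSet],
                         ) -> dict[str, object]:
    """Do TF sources regulate multiple transcripts more than chance?

    The adopted statistic is the number of sources with two or more distinct
    targets; its permutation p-value counts permuted sets reaching at least
    the real statistic.  The per-source target-count vectors (real and pooled
    permuted) are also compared by Wilcoxon rank-sum and returned raw, so a
    different multiplicity reading costs one line downstream.
    """
    if not permuted_sets:
        raise InvalidParameterError("need at least one permuted set")
    real_stat, real_counts = _multi_target_count(real_tf_pairs)
    perm_stats = []
    pooled: list[int] = []
    for ps in permuted_sets:
        s, counts = _multi_target_count(ps.pairs)
        perm_stats.append(s)
        pooled.extend(counts)
    perm_stats_arr = np.asarray(perm_stats)
    emp_p = float((perm_stats_arr >= real_stat).mean())
    wilcoxon_p = float(stats.mannwhitneyu(real_counts, pooled,
                                      alternative="greater").pvalue)
    return {
        "statistic": int(real_stat),
        "empirical_p": emp_p,
        "wilcoxon_p": wilcoxon_p,
        "real_target_counts": real_counts,
        "permuted_statistics": perm_stats_arr,
    }


def sample_length_matched_paths(pool: Sequence[PathRecord],
                                real_lengths: Sequence[int],
                                n_sets: int = 1000, seed: int = 0,
                                ) -> list[list[PathRecord]]:
    """Permuted path sets matching the real path-length multiset exactly.

    Each set is drawn without replacement from ``pool``; draws are
    independent across sets.  Raises :class:`FeasibilityError` naming the
    first length for which the pool is too shallow.
    """
    if n_sets < 1:
        raise InvalidParameterError("n_sets must be positive")
    need = Counter(int(l) for l in real_lengths)
    by_length: dict[int, list[PathRecord]] = {}
    for p in pool:
        by_length.setdefault(p.length, []).append(p)
    for length, k in sorted(need.items()):
        have = len(by_length.get(length, []))
        if have < k:
            raise FeasibilityError(
                f"pool has {have} paths of length {length}, need {k}")
    out: list[list[PathRecord]] = []
    for k in range(n_sets):
        rng = np.random.default_rng(derive_seed(seed, "length_matched_paths", k))
        chosen: list[PathRecord] = []
        for length, count in sorted(need.items()):
            candidates = by_length[length]
            idx = rng.choice(len(candidates), size=count, replace=False)
            chosen.extend(candidates[i] for i in idx)
        out.append(chosen)
    return out
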