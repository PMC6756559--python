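"""Exhaustive, random and sampled generation of BTC networks over [n].

Every BTC network over ``[n]`` arises from the trivial network by a unique
chain of ``n - 1`` augmentations adding the leaves ``2, 3, ..., n`` in
order, so a depth-first expansion over feasible pairs enumerates the whole
class *with unicity* — no isomorphism filtering is needed.  The expansion
streams with copy-on-augment, keeping memory proportional to the depth
times the network size, which is what makes count-only runs at n = 5
(496,710 networks) routine and n = 6 (101,833,875) possible given hours.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from typing import Iterator

from .augmentation import augment, enumerate_feasible_pairs
from .network import PhyloNetwork

__all__ = [
    "generate_all",
    "count_networks",
    "count_by_hybrids",
    "random_network",
    "estimate_next_count",
]


def _expand(net: PhyloNetwork, next_label: int, n: int) -> Iterator[PhyloNetwork]:
    if next_label > n:
        yield net
        return
    for s1, s2 in enumerate_feasible_pairs(net):
        child = augment(net, next_label, s1, s2, check=False)
        yield from _expand(child, next_label + 1, n)


def generate_all(n: int) -> Iterator[PhyloNetwork]:
    """Yield every BTC network over ``[n]`` exactly once.

    Networks are produced in the deterministic depth-first order induced by
    the feasible-pair enumeration; consuming the iterator without retaining
    networks is the count-only mode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    yield from _expand(PhyloNetwork.trivial(1), 2, n)


def count_networks(n: int) -> int:
    """``|BTC_n|`` by exhaustive streaming generation."""
    return sum(1 for _ in generate_all(n))


def count_by_hybrids(n: int) -> dict[int, int]:
    """Exact per-hybrid-count census ``h -> B(n, h)`` of ``BTC_n``.

    The support is contained in ``{0, ..., n-1}`` and the values sum to
    ``|BTC_n|``.
    """
    counts: Counter[int] = Counter()
    for net in generate_all(n):
        counts[net.num_hybrid()] += 1
    return dict(sorted(counts.items()))


def random_network(n: int, seed: int) -> PhyloNetwork:
    """A seeded random BTC network over ``[n]``.

    At each of the ``n - 1`` steps all feasible pairs of the current
    network are enumerated and one is drawn uniformly with a dedicated
    ``random.Random(seed)`` stream.  Every network of ``BTC_n`` has positive
    probability, but the scheme is *not* uniform over ``BTC_n``: networks
    differ in how many feasible pairs their ancestors expose.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    net = PhyloNetwork.trivial(1)
    for label in range(2, n + 1):
        pairs = list(enumerate_feasible_pairs(net))
        s1, s2 = pairs[rng.randrange(len(pairs))]
        net = augment(net, label, s1, s2, check=False)
    return net


def estimate_next_count(
    n: int, sample_size: int, seed: int
) -> tuple[float, float]:
    """Sampling estimate of ``|BTC_{n+1}|`` with its standard error.

    ``BTC_n`` is materialized so networks can be sampled uniformly (with
    replacement); each sampled network contributes its offspring count —
    its number of feasible pairs — and the estimate is the sample mean
    scaled by ``|BTC_n|``.  A ``sample_size`` at least ``|BTC_n|`` clamps
    to the exhaustive sum, which is exact (standard error 0).
    """
    nets = list(generate_all(n))
    total = len(nets)
    offspring = lambda net: sum(1 for _ in enumerate_feasible_pairs(net))
    if sample_size >= total:
        return float(sum(offspring(net) for net in nets)), 0.0
    rng = random.Random(seed)
    counts = [offspring(nets[rng.randrange(total)]) for _ in range(sample_size)]
    mean = sum(counts) / sample_size
    var = sum((c - mean) ** 2 for c in counts) / (sample_size - 1)
    return mean * total, math.sqrt(var / sample_size) * total
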