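"""Placement of a new sequence into a sequenced BTC network.

Given a BTC network whose tree nodes carry aligned fixed-length sequences,
and a new taxon known only by its sequence, the heuristic chooses the
augmentation operation — and the sequences of the nodes it creates — that
best explains the data under a supplied evolution model:

1. the best T-attachment subdivides the arc entering some tree node
   ``tau_1`` with a new node whose inferred sequence maximizes
   ``pi(t) = phi_t(sigma) * P_S(sigma, s(t)) * P_S(sigma, s_l)``;
2. the best H-attachment hangs the new leaf below a hybrid node fed from
   the subdivided arcs above an unordered pair of tree nodes;
3. whichever scores higher wins (T on ties);
4. hybridizations ``y_1, y_2, ...`` feeding existing lineages from the new
   leaf's lineage are then added greedily while the gain ``kappa`` over
   the no-hybridization explanation is non-negative.

No claim of global optimality is made: the procedure is stepwise greedy by
construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Iterator, Optional

from .augmentation import augment_with_detail, check_feasible
from .network import PhyloNetwork, validate

__all__ = [
    "SequencedNetwork",
    "EvolutionModel",
    "ToyRecombinationModel",
    "toy_model",
    "PlacementTrace",
    "phi",
    "select_attachment",
    "extend_with_hybridizations",
    "place_sequence",
]


@dataclass
class SequencedNetwork:
    """A BTC network whose tree nodes carry aligned sequences.

    Hybrid nodes carry no sequence: the sequence emerging from a reticulate
    event lives at the hybrid node's single (tree) child.
    """

    network: PhyloNetwork
    sequences: dict[int, str]

    def check(self) -> None:
        net = self.network
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths {lengths}")
        for u in net.nodes:
            if net.is_tree_node(u) and u not in self.sequences:
                raise ValueError(f"tree node {u} has no sequence")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


class EvolutionModel:
    """Probability kernels for descent (``P_S``) and hybridization (``P_H``),
    plus the search strategy used to maximize products of kernels over
    candidate sequences.

    The default strategy is exhaustive search over ``sequence_space()`` in
    lexicographic order, keeping the first maximum — so ties resolve to
    the lexicographically smallest sequence.  Models over large spaces can
    override :meth:`argmax` (e.g. with hill climbing).
    """

    def p_s(self, s: str, s2: str) -> float:
        raise NotImplementedError

    def p_h(self, s1: str, s2: str, s3: str) -> float:
        raise NotImplementedError

    def sequence_space(self) -> Iterator[str]:
        raise NotImplementedError

    def argmax(self, objective: Callable[[str], float]) -> tuple[str, float]:
        best, best_val = None, -1.0
        for sigma in self.sequence_space():
            val = objective(sigma)
            if val > best_val:
                best, best_val = sigma, val
        return best, best_val

    def argmax_pair(
        self, objective: Callable[[str, str], float]
    ) -> tuple[tuple[str, str], float]:
        best, best_val = None, -1.0
        for sigma1 in self.sequence_space():
            for sigma2 in self.sequence_space():
                val = objective(sigma1, sigma2)
                if val > best_val:
                    best, best_val = (sigma1, sigma2), val
        return best, best_val


class ToyRecombinationModel(EvolutionModel):
    """Jukes–Cantor-style point mutation plus half-sequence recombination.

    Speciation: ``P_S(s, s') = mu^d * (1 - (q-1) mu)^(L-d)`` with ``d`` the
    Hamming distance, ``q`` the alphabet size and ``mu`` the per-site
    mutation probability; ``mu < 1/q`` so that staying put is more likely
    than any specific change.  Hybridization is plain recombination: the
    hybrid sequence takes one half from each parent, each of the two
    half-splices having probability 1/2.
    """

    def __init__(self, mu: float, length: int = 4, alphabet: str = "ABC") -> None:
        q = len(alphabet)
        if len(set(alphabet)) != q or q < 2:
            raise ValueError("alphabet must have at least 2 distinct symbols")
        if not 0.0 < mu < 1.0 / q:
            raise ValueError(
                f"mu must lie in (0, 1/{q}) for a {q}-letter alphabet, got {mu}"
            )
        if length % 2:
            raise ValueError("sequence length must be even for the half-split")
        self.mu = mu
        self.length = length
        self.alphabet = alphabet

    def p_s(self, s: str, s2: str) -> float:
        d = sum(a != b for a, b in zip(s, s2))
        stay = 1.0 - (len(self.alphabet) - 1) * self.mu
        return self.mu**d * stay ** (self.length - d)

    def p_h(self, s1: str, s2: str, s3: str) -> float:
        half = self.length // 2
        r1 = s1[:half] + s2[half:]
        r2 = s2[:half] + s1[half:]
        return 0.5 if s3 in (r1, r2) else 0.0

    def sequence_space(self) -> Iterator[str]:
        for tup in itertools.product(self.alphabet, repeat=self.length):
            yield "".join(tup)


def toy_model(mu: float, length: int = 4, alphabet: str = "ABC") -> ToyRecombinationModel:
    return ToyRecombinationModel(mu, length=length, alphabet=alphabet)


def phi(snet: SequencedNetwork, t: int, s: str, model: EvolutionModel) -> float:
    """Probability that sequence ``s`` arises at tree node ``t`` from its
    parent (or, across a hybrid parent, from its two grandparents); 1 at
    the root, which has nothing above it."""
    net = snet.network
    parents = net.parents(t)
    if not parents:
        return 1.0
    p = parents[0]
    if net.is_hybrid(p):
        g1, g2 = sorted(net.parents(p))
        return model.p_h(snet.sequences[g1], snet.sequences[g2], s)
    return model.p_s(snet.sequences[p], s)


@dataclass
class PlacementTrace:
    """Everything the heuristic decided, for inspection and serialization."""

    kind: str  # "T" | "H"
    s1: tuple[int, ...]
    sigmas: tuple[str, ...]
    pi: float
    pi_t: float
    pi_h: float
    t_scores: dict[int, tuple[str, float]] = field(default_factory=dict)
    h_scores: dict[tuple[int, int], tuple[str, str, float]] = field(default_factory=dict)
    accepted: list[tuple[int, str, float]] = field(default_factory=list)
    rounds: list[dict[int, tuple[str, float, float]]] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "kind": self.kind,
            "S1": list(self.s1),
            "sigmas": list(self.sigmas),
            "pi": self.pi,
            "pi_T": self.pi_t,
            "pi_H": self.pi_h,
            "T_scores": {str(t): [s, v] for t, (s, v) in self.t_scores.items()},
            "H_scores": {
                f"{a},{b}": [s1, s2, v]
                for (a, b), (s1, s2, v) in self.h_scores.items()
            },
            "accepted": [[y, s, k] for y, s, k in self.accepted],
            "rounds": [
                {str(y): [s, p, k] for y, (s, p, k) in rnd.items()}
                for rnd in self.rounds
            ],
        }


def _attachment_candidates(net: PhyloNetwork) -> list[int]:
    # The pi score prices the subdivision of the arc entering a node, so
    # candidates are the tree nodes that have one; only the trivial network
    # has none, and there its single node anchors the only possible cherry.
    cands = [u for u in net.nodes if net.is_tree_node(u) and net.indegree(u) == 1]
    return cands if cands else [net.root()]


def select_attachment(
    snet: SequencedNetwork, s_l: str, model: EvolutionModel
) -> PlacementTrace:
    """Score every T-anchor and every unordered H-anchor pair, and pick the
    winner (T wins ties).  Ties between anchors resolve to the smallest
    node id; ties between sequences to the lexicographically smallest."""
    net = snet.network
    if net.num_nodes == 0:
        raise ValueError("empty network")
    snet.check()
    cands = _attachment_candidates(net)

    t_scores: dict[int, tuple[str, float]] = {}
    for t in cands:
        st = snet.sequences[t]
        sigma, val = model.argmax(
            lambda s: phi(snet, t, s, model) * model.p_s(s, st) * model.p_s(s, s_l)
        )
        t_scores[t] = (sigma, val)
    tau_t = max(t_scores, key=lambda t: t_scores[t][1])
    # max() keeps the first (smallest-id) argmax on ties
    sigma_t, pi_t = t_scores[tau_t]

    h_scores: dict[tuple[int, int], tuple[str, str, float]] = {}
    for t1, t2 in itertools.combinations(cands, 2):
        s1, s2 = snet.sequences[t1], snet.sequences[t2]

        def objective(a: str, b: str, _t1=t1, _t2=t2, _s1=s1, _s2=s2) -> float:
            ph = model.p_h(a, b, s_l)
            if ph == 0.0:
                return 0.0
            return (
                phi(snet, _t1, a, model)
                * model.p_s(a, _s1)
                * phi(snet, _t2, b, model)
                * model.p_s(b, _s2)
                * ph
            )

        (sa, sb), val = model.argmax_pair(objective)
        h_scores[(t1, t2)] = (sa, sb, val)
    if h_scores:
        tau_h = max(h_scores, key=lambda p: h_scores[p][2])
        sa, sb, pi_h = h_scores[tau_h]
    else:
        tau_h, sa, sb, pi_h = None, "", "", 0.0

    if pi_t >= pi_h:
        trace = PlacementTrace(
            kind="T", s1=(tau_t,), sigmas=(sigma_t,), pi=pi_t, pi_t=pi_t, pi_h=pi_h
        )
    else:
        trace = PlacementTrace(
            kind="H", s1=tau_h, sigmas=(sa, sb), pi=pi_h, pi_t=pi_t, pi_h=pi_h
        )
    trace.t_scores = t_scores
    trace.h_scores = h_scores
    return trace


def extend_with_hybridizations(
    snet: SequencedNetwork, trace: PlacementTrace, s_l: str, model: EvolutionModel
) -> PlacementTrace:
    """Greedily grow ``S2``: at round ``k`` every tree node ``y`` keeping
    ``(S1, (y_1 .. y_{k-1}, y))`` feasible is scored, candidates whose gain
    ``kappa`` over the hybridization-free explanation is negative are
    dropped, and the best survivor (if any) becomes ``y_k``."""
    net = snet.network
    s1 = trace.s1
    while True:
        k = len(trace.accepted) + 1
        ys = tuple(y for y, _, _ in trace.accepted)
        round_scores: dict[int, tuple[str, float, float]] = {}
        for y in net.nodes:
            if not net.is_tree_node(y) or not net.parents(y):
                continue
            result = check_feasible(net, s1, ys + (y,))
            if result.kind != trace.kind:
                continue
            p = net.parents(y)[0]
            if net.is_hybrid(p):
                # The printed score needs the parent's own sequence; a hybrid
                # parent has none and the adapted formula is not specified.
                warnings.warn(
                    f"skipping candidate {y}: parent is a hybrid node",
                    stacklevel=2,
                )
                continue
            sp, sy = snet.sequences[p], snet.sequences[y]
            if k == 1 and trace.kind == "H":
                sig1, sig2 = trace.sigmas

                def objective(s: str) -> float:
                    return (
                        model.p_h(sig1, sig2, s)
                        * model.p_h(s, sp, sy)
                        * model.p_s(s, s_l)
                    )

                alternative = model.p_s(sp, sy) * model.p_h(sig1, sig2, s_l)
            else:
                prev_sigma = trace.accepted[-1][1] if trace.accepted else trace.sigmas[0]

                def objective(s: str) -> float:
                    return (
                        model.p_s(prev_sigma, s)
                        * model.p_h(s, sp, sy)
                        * model.p_s(s, s_l)
                    )

                alternative = model.p_s(sp, sy) * model.p_s(prev_sigma, s_l)
            sigma, pi_y = model.argmax(objective)
            kappa = pi_y - alternative
            if kappa >= 0.0:
                round_scores[y] = (sigma, pi_y, kappa)
        trace.rounds.append(round_scores)
        if not round_scores:
            return trace
        y_k = max(round_scores, key=lambda y: round_scores[y][2])
        sigma, _, kappa = round_scores[y_k]
        trace.accepted.append((y_k, sigma, kappa))


def place_sequence(
    snet: SequencedNetwork,
    label: Hashable,
    s_l: str,
    model: EvolutionModel,
) -> tuple[SequencedNetwork, PlacementTrace]:
    """Run the full heuristic and materialize the augmented network.

    Pre-existing tree nodes keep their sequences; the split nodes above the
    anchors, the new path nodes and the new leaf get the inferred
    sequences; hybrid nodes get none.  The output network is validated.
    """
    if label in snet.network.labels.values():
        raise ValueError(f"label {label!r} already present")
    trace = select_attachment(snet, s_l, model)
    trace = extend_with_hybridizations(snet, trace, s_l, model)

    s2 = tuple(y for y, _, _ in trace.accepted)
    new_net, detail = augment_with_detail(snet.network, label, trace.s1, s2)
    report = validate(new_net)
    if not report.ok:
        raise AssertionError(f"placement produced an invalid network: {report.violations}")

    sequences = dict(snet.sequences)
    for w, sigma in zip(detail.w, trace.sigmas):
        sequences[w] = sigma
    for u, (_, sigma, _) in zip(detail.us, trace.accepted):
        sequences[u] = sigma
    sequences[detail.us[-1]] = s_l
    out = SequencedNetwork(network=new_net, sequences=sequences)
    out.check()
    return out, trace
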