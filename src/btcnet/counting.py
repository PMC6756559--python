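"""Closed-form pair counts and the recursive upper bound on |BTC_n|.

A BTC network with ``n`` leaves and ``h`` hybrid nodes has ``t = 2n + h - 1``
tree nodes.  The number of pairs ``(S1, S2)`` satisfying the feasibility
conditions *except* the descent condition (condition 3) depends only on
``(n, h, |S2|)`` and has a closed form, built from the auxiliary count
``p(n, h, k)`` of length-``k`` tuples of tree nodes that are pairwise
neither equal nor siblings and have no hybrid parent or sibling.  Summing
the closed forms over the possible parent classes gives a recursion whose
totals upper-bound ``|BTC_n|`` (dropping condition 3 only ever adds pairs,
some of which would create cycles).

All arithmetic is exact big-integer; the factorial-ratio formulas are
implemented as falling-factorial products with every non-positive factor
clamping its term to zero, which is the convention under which the
recursion is well defined for degenerate arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["p0", "p1", "p_tuples", "f_H", "f_T", "BoundTable", "bound_table"]


def p0(n: int, h: int, k: int) -> int:
    """Tuples avoiding the root: ``prod_{j=1..k} (2n - 2h - 2j)``.

    Zero as soon as any factor is non-positive; 1 for the empty tuple;
    0 for negative ``k`` (no tuple has negative length).
    """
    if k < 0:
        return 0
    out = 1
    for j in range(1, k + 1):
        factor = 2 * n - 2 * h - 2 * j
        if factor <= 0:
            return 0
        out *= factor
    return out


def p1(n: int, h: int, k: int) -> int:
    """Tuples containing the root: the root takes one of ``k`` positions and
    the rest form a root-free tuple of length ``k - 1``."""
    if k < 0:
        return 0
    return k * p0(n, h, k - 1)


def p_tuples(n: int, h: int, k: int) -> int:
    """``p(n, h, k)``: tuples of ``k`` tree nodes, pairwise neither equal nor
    siblings, none with a hybrid parent or hybrid sibling."""
    return p0(n, h, k) + p1(n, h, k)


def _pos(x: int) -> int:
    return x if x > 0 else 0


def f_H(n: int, h: int, k: int) -> int:
    """Pairs satisfying conditions 1, 2 and 4H with ``|S2| = k`` (``r = k+1``).

    The tuple ``S2`` is drawn from ``p(n, h, k)``; the two anchors are a
    single tree node taken twice (``F_H,1``) or an unordered pair of
    distinct tree nodes (``F_H,2``) among the ``2n + h - r`` tree nodes not
    in ``S2``.
    """
    r = k + 1
    m = 2 * n + h - r
    pk = p_tuples(n, h, k)
    fh1 = pk * _pos(m)
    fh2 = pk * (_pos(m) * _pos(m - 1)) // 2
    return fh1 + fh2


def f_T(n: int, h: int, k: int) -> int:
    """Pairs satisfying conditions 1, 2 and 4T with ``|S2| = k`` (``r = k+1``).

    Four mutually exclusive cases by the role of the single anchor tau_1:
    outside ``S2``; inside ``S2`` as a child or sibling of a hybrid node
    (3h choices); inside ``S2`` as the sibling of another ``S2`` member
    (split by whether the remaining tuple contains the root); or inside
    ``S2`` with none of these coincidences.
    """
    r = k + 1
    m = 2 * n + h - r
    ft1 = p_tuples(n, h, k) * _pos(m)
    ft2 = p_tuples(n, h, k - 1) * k * 3 * h
    ft3 = k * (k - 1) * (
        p1(n, h, k - 2) * _pos(2 * n - 2 * h - 2 * r + 6)
        + p0(n, h, k - 2) * _pos(2 * n - 2 * h - 2 * r + 4)
    )
    ft4 = p_tuples(n, h, k) * k
    return ft1 + ft2 + ft3 + ft4


@dataclass
class BoundTable:
    """The recursion table ``B(n, h)`` and its row totals.

    ``B(1, 0) = 1`` and each ``B(n, h)`` sums, over the parent's hybrid
    count ``h'``, the parent bound times the closed-form pair counts that
    raise ``h'`` to ``h`` (T-augmentations add ``|S2|`` hybrids,
    H-augmentations ``|S2| + 1``).  ``totals(n)`` upper-bounds ``|BTC_n|``.
    """

    n_max: int
    B: dict[tuple[int, int], int]
    totals: dict[int, int]

    def rows(self):
        for n in range(1, self.n_max + 1):
            for h in range(0, n):
                yield n, h, self.B.get((n, h), 0)


def bound_table(n_max: int) -> BoundTable:
    """Compute ``B(n, h)`` for ``n <= n_max`` with exact integers."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    B: dict[tuple[int, int], int] = {(1, 0): 1}
    for n in range(2, n_max + 1):
        for h in range(0, n):
            total = 0
            for hp in range(0, h + 1):
                total += B.get((n - 1, hp), 0) * f_T(n - 1, hp, h - hp)
            for hp in range(0, h):
                total += B.get((n - 1, hp), 0) * f_H(n - 1, hp, h - hp - 1)
            B[(n, h)] = total
    totals = {
        n: sum(B.get((n, h), 0) for h in range(0, n)) for n in range(1, n_max + 1)
    }
    return BoundTable(n_max=n_max, B=B, totals=totals)
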