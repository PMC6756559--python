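"""Readers and writers for network and sequence formats.

Two text formats are supported for networks:

* **extended Newick (eNewick)** — each hybrid node appears twice under a
  shared ``#Hk`` tag; its child subtree is written at exactly one of the
  occurrences (the first reached in deterministic traversal order), the
  other occurrence is a bare tag.  Dialects of eNewick vary; this is the
  common one.
* **edge list** — a TSV of ``A <parent> <child>`` arc rows and
  ``L <node> <label>`` leaf rows.  Unlike eNewick it preserves node ids,
  so it is the lossless interchange format.

Sequences for placement travel as FASTA (via Bio.SeqIO), keyed by node
name: leaf records by their label, internal tree nodes by the names given
in the eNewick string.
"""

from __future__ import annotations

import io as _stdio
import re
from typing import Hashable, TextIO

from Bio import SeqIO

from .network import PhyloNetwork, validate

__all__ = [
    "write_enewick",
    "read_enewick",
    "read_enewick_named",
    "write_edgelist",
    "read_edgelist",
    "read_sequences_fasta",
    "write_sequences_fasta",
]


class EnewickError(ValueError):
    """Malformed eNewick input (with the offending position when known)."""


def write_enewick(net: PhyloNetwork) -> str:
    """Serialize a valid BTC network to an eNewick string.

    Hybrid tags ``#H1..#Hk`` are assigned in increasing node-id order, and
    children are written in stored arc order, so output is deterministic
    for a given network object.
    """
    report = validate(net)
    if not report.ok:
        raise ValueError(f"refusing to serialize invalid network: {report.violations}")
    hybrids = [u for u in net.nodes if net.is_hybrid(u)]
    tag = {u: f"#H{i + 1}" for i, u in enumerate(hybrids)}
    written: set[int] = set()

    def render(u: int) -> str:
        if net.is_hybrid(u):
            if u in written:
                return tag[u]
            written.add(u)
            child = net.children(u)[0]
            return f"({render(child)}){tag[u]}"
        if net.is_leaf(u):
            return str(net.labels[u])
        inner = ",".join(render(c) for c in net.children(u))
        return f"({inner})"

    return render(net.root()) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;#\s]+|#[^(),;\s]+|\s+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise EnewickError(f"unexpected character at position {pos}")
        if not m.group().isspace():
            tokens.append((m.group(), m.start()))
        pos = m.end()
    if pos != len(text):
        raise EnewickError(f"unexpected character at position {pos}")
    return tokens


def _parse_label(raw: str) -> Hashable:
    return int(raw) if raw.isdigit() else raw


def read_enewick_named(
    text: str, strict: bool = True
) -> tuple[PhyloNetwork, dict[str, int]]:
    """Parse eNewick into a network plus a name -> node map.

    The map covers leaf labels and any internal-node names present in the
    input (hybrid tags themselves are not names).  With ``strict`` the
    result must be a valid BTC network; otherwise validation problems are
    reported via the returned network's own :func:`validate`.
    """
    tokens = _tokenize(text)
    if not tokens or tokens[-1][0] != ";":
        raise EnewickError("input must end with ';'")
    tokens = tokens[:-1]
    net = PhyloNetwork()
    names: dict[str, int] = {}
    tag_nodes: dict[str, list[tuple[int, bool]]] = {}  # tag -> [(node, has_child)]
    i = 0

    def parse_subtree() -> int:
        nonlocal i
        children: list[int] = []
        if i < len(tokens) and tokens[i][0] == "(":
            i += 1
            children.append(parse_subtree())
            while i < len(tokens) and tokens[i][0] == ",":
                i += 1
                children.append(parse_subtree())
            if i >= len(tokens) or tokens[i][0] != ")":
                pos = tokens[i - 1][1] if i else 0
                raise EnewickError(f"expected ')' near position {pos}")
            i += 1
        name = None
        tag = None
        while i < len(tokens) and tokens[i][0] not in "(),":
            tok = tokens[i][0]
            if tok.startswith("#"):
                tag = tok
            else:
                name = tok
            i += 1
        if not children and name is None and tag is None:
            pos = tokens[i][1] if i < len(tokens) else len(text)
            raise EnewickError(f"empty subtree near position {pos}")
        u = net.add_node()
        for c in children:
            net.add_arc(u, c)
        if tag is not None:
            tag_nodes.setdefault(tag, []).append((u, bool(children)))
            if name is not None:
                names[name] = u
        elif name is not None:
            if children:
                names[name] = u
            else:
                net.set_label(u, _parse_label(name))
                names[name] = u
        return u

    root = parse_subtree()
    if i != len(tokens):
        raise EnewickError(f"trailing input at position {tokens[i][1]}")

    # merge the occurrences of each hybrid tag into a single node
    for tag, occ in tag_nodes.items():
        with_child = [u for u, has in occ if has]
        if len(occ) < 2 or len(with_child) != 1:
            raise EnewickError(
                f"hybrid tag {tag} must occur at least twice, exactly once "
                f"with a child subtree"
            )
        keep = with_child[0]
        for u, has in occ:
            if u == keep:
                continue
            if u == root:
                raise EnewickError(f"hybrid tag {tag} at root")
            for p in list(net.parents(u)):
                net.remove_arc(p, u)
                net.add_arc(p, keep)
            net.remove_node(u)
            for nm, v in list(names.items()):
                if v == u:
                    names[nm] = keep

    report = validate(net)
    if strict and not report.ok:
        raise ValueError(f"parsed graph is not a BTC network: {report.violations}")
    return net, names


def read_enewick(text: str, strict: bool = True) -> PhyloNetwork:
    net, _ = read_enewick_named(text, strict=strict)
    return net


def write_edgelist(net: PhyloNetwork) -> str:
    lines = ["# btcnet edge list: A parent child / L node label"]
    for u, v in net.arcs():
        lines.append(f"A\t{u}\t{v}")
    for u in sorted(net.labels):
        lines.append(f"L\t{u}\t{net.labels[u]}")
    return "\n".join(lines) + "\n"


def read_edgelist(text: str) -> PhyloNetwork:
    arcs: list[tuple[int, int]] = []
    labels: dict[int, Hashable] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "A" and len(parts) == 3:
            arcs.append((int(parts[1]), int(parts[2])))
        elif parts[0] == "L" and len(parts) == 3:
            labels[int(parts[1])] = _parse_label(parts[2])
        else:
            raise ValueError(f"bad edge-list row at line {lineno}: {line!r}")
    return PhyloNetwork.from_arcs(arcs, labels)


def read_sequences_fasta(
    handle: TextIO, names: dict[str, int]
) -> dict[int, str]:
    """Read node sequences from FASTA, resolving record ids via ``names``."""
    sequences: dict[int, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        if record.id not in names:
            raise KeyError(f"FASTA record {record.id!r} names no network node")
        sequences[names[record.id]] = str(record.seq)
    return sequences


def write_sequences_fasta(sequences: dict[int, str], names: dict[str, int]) -> str:
    by_node = {v: k for k, v in names.items()}
    out = _stdio.StringIO()
    for u in sorted(sequences):
        out.write(f">{by_node.get(u, f'node{u}')}\n{sequences[u]}\n")
    return out.getvalue()
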