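"""Phylogeny container, newick I/O in the PAML label dialect, pruning and RF.

The tree dialect used throughout is newick extended with PAML foreground
labels: a token ``#k`` (branch) or ``$k`` (clade) may follow a leaf name or
a closing parenthesis, before the ``:length`` field, e.g.::

    ((A,B) #1, (C,D) $2);

Labels are first-class here — they survive parsing, pruning and writing —
because CodeML reads the rate-class structure of a branch model from them.

Robinson–Foulds distances are computed on unrooted nontrivial split sets
and normalized by the total number of nontrivial splits of both trees, so
multifurcating (partially unresolved) trees normalize gracefully.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

_LABEL_RE = re.compile(r"^[#$][0-9]+$")


class TreeError(ValueError):
    """Malformed newick or an operation violating tree invariants."""


@dataclass
class Node:
    name: Optional[str] = None
    length: Optional[float] = None
    label: Optional[str] = None  # PAML token "#k" or "$k"
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class Phylogeny:
    """Rooted-as-written tree; polytomies permitted; leaf names unique."""

    def __init__(self, root: Node):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise TreeError("unnamed leaf")
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf names: {dup}")

    # --- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def leaf_order(self) -> list[str]:
        """Leaf names in newick (left-to-right) appearance order."""
        return [leaf.name for leaf in self.leaves()]

    def n_edges(self) -> int:
        return sum(1 for n in self.preorder() if n.parent is not None)

    def descendant_leaf_sets(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> descendant leaf-name set, for every node."""
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.name])
            else:
                acc: frozenset[str] = frozenset()
                for child in node.children:
                    acc |= sets[id(child)]
                sets[id(node)] = acc
        return sets

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise TreeError(f"no leaf named {name!r}")

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, length=node.length, label=node.label)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny({write_newick(self)})"


# --- parsing -------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse newick, retaining branch lengths and PAML ``#k``/``$k`` tokens.

    Raises TreeError with the character position on unbalanced parentheses
    or other syntax errors, and on duplicate leaf names.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def error(msg: str) -> TreeError:
        return TreeError(f"newick parse error at position {pos}: {msg}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= len(s):
                    raise error("unbalanced parentheses (unexpected end)")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', found {s[pos]!r}")
        # optional name (leaves; also tolerated as internal node name)
        skip_ws()
        start = pos
        while pos < len(s) and s[pos] not in "(),:;#$" and not s[pos].isspace():
            pos += 1
        if pos > start:
            node.name = s[start:pos]
        # optional PAML label token
        skip_ws()
        if pos < len(s) and s[pos] in "#$":
            tstart = pos
            pos += 1
            while pos < len(s) and s[pos].isdigit():
                pos += 1
            token = s[tstart:pos]
            if not _LABEL_RE.match(token):
                raise error(f"malformed label token {token!r}")
            node.label = token
        # optional branch length
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            skip_ws()
            lstart = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                node.length = float(s[lstart:pos])
            except ValueError:
                raise error("invalid branch length") from None
        # label may also follow the length in some writers
        skip_ws()
        if pos < len(s) and s[pos] in "#$" and node.label is None:
            tstart = pos
            pos += 1
            while pos < len(s) and s[pos].isdigit():
                pos += 1
            node.label = s[tstart:pos]
        if node.is_leaf and node.name is None:
            raise error("unnamed leaf")
        return node

    root = parse_clade()
    skip_ws()
    if pos != len(s):
        raise error(f"trailing characters {s[pos:]!r}")
    return Phylogeny(root)


def write_newick(
    tree: Phylogeny, include_labels: bool = True, include_lengths: bool = True
) -> str:
    """Write newick; PAML tokens are emitted as `` #k``/`` $k`` after the
    subtree (or leaf name), before any branch length."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                out += node.name
        if include_labels and node.label:
            out += f" {node.label}"
        if include_lengths and node.length is not None:
            out += f":{node.length:g}"
        return out

    return fmt(tree.root) + ";"


# --- pruning -------------------------------------------------------------


def prune_to_taxa(tree: Phylogeny, keep: frozenset[str] | set[str]) -> Phylogeny:
    """Restrict a tree to a taxon subset.

    Unifurcations left by leaf removal are suppressed with their branch
    lengths summed, preserving leaf-to-leaf path lengths; PAML labels on a
    suppressed node are transferred to its surviving child only if the child
    carries none (explicit labels win).  Polytomies are preserved.
    """
    keep = frozenset(keep)
    missing = keep - tree.leaf_names
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError(f"cannot prune to fewer than 2 taxa (got {len(keep)})")

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.name in keep:
                return Node(name=node.name, length=node.length, label=node.label)
            return None
        kept = [c for c in (prune(child) for child in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress the unifurcation: splice child upward, summing lengths
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if child.label is None:
                child.label = node.label
            return child
        new = Node(name=node.name, length=node.length, label=node.label)
        for c in kept:
            new.add_child(c)
        return new

    root = prune(tree.root)
    assert root is not None  # |keep| >= 2 guarantees survivors
    if root.is_leaf:  # cannot happen with |keep| >= 2
        raise TreeError("pruning collapsed the tree to a single leaf")
    root.length = None  # a root branch has no meaning after re-rooting
    return Phylogeny(root)


# --- bipartitions & Robinson-Foulds --------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial unrooted split, canonicalized as the side that does not
    contain the lexicographically smallest taxon."""

    side: frozenset[str]

    @classmethod
    def from_clade(cls, clade: frozenset[str], all_taxa: frozenset[str]) -> Optional["Bipartition"]:
        other = all_taxa - clade
        if len(clade) < 2 or len(other) < 2:
            return None  # trivial
        anchor = min(all_taxa)
        side = other if anchor in clade else clade
        return cls(side=side)


@dataclass(frozen=True)
class TreeComparison:
    rf_raw: int
    rf_normalized: float


def bipartitions(tree: Phylogeny) -> frozenset[Bipartition]:
    """Nontrivial unrooted splits, one per internal edge (root ignored)."""
    taxa = tree.leaf_names
    sets = tree.descendant_leaf_sets()
    out: set[Bipartition] = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        bp = Bipartition.from_clade(sets[id(node)], taxa)
        if bp is not None:
            out.add(bp)
    return frozenset(out)


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> TreeComparison:
    """Robinson–Foulds distance on unrooted split sets.

    raw = |symmetric difference|; normalized = raw / (|splits1| + |splits2|),
    defined as 0.0 when both trees are stars (no nontrivial splits).
    """
    if t1.leaf_names != t2.leaf_names:
        only1 = sorted(t1.leaf_names - t2.leaf_names)
        only2 = sorted(t2.leaf_names - t1.leaf_names)
        raise TreeError(f"leaf sets differ (only in first: {only1}; only in second: {only2})")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    raw = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return TreeComparison(rf_raw=raw, rf_normalized=(raw / denom) if denom else 0.0)


# --- random trees (fixture support) --------------------------------------


def random_binary_tree(
    taxa: list[str], rng, lengths: Callable[[], float] | None = None
) -> Phylogeny:
    """Random rooted binary topology by sequential attachment; used by the
    fixture generator and property tests."""
    if len(taxa) < 2:
        raise TreeError("need at least 2 taxa")
    draw = lengths if lengths is not None else (lambda: float(rng.uniform(0.02, 0.3)))
    nodes = [Node(name=t, length=draw()) for t in taxa]
    order = list(rng.permutation(len(nodes)))
    pool = [nodes[i] for i in order]
    while len(pool) > 1:
        i = int(rng.integers(len(pool)))
        a = pool.pop(i)
        j = int(rng.integers(len(pool)))
        b = pool.pop(j)
        parent = Node(length=draw())
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    pool[0].length = None
    return Phylogeny(pool[0])
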