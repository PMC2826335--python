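"""Unrooted trees with branch lengths and bootstrap bipartition supports.

A :class:`SupportTree` is stored as an adjacency map over integer node ids;
leaves carry accession (or section) labels.  Bipartitions are canonicalized
as the split side *not* containing the lexicographically smallest leaf, so a
split compares equal across trees regardless of rooting or rotation.

The Newick dialect writes branch lengths with six decimals and bootstrap
supports as integer-percent internal-node labels, the convention most tree
viewers expect for NJ dendrograms.
"""

from __future__ import annotations

from typing import Iterator

from .errors import ValidationError
from ._util import round_half_up

Split = frozenset  # of leaf labels; canonical side of a bipartition


class SupportTree:
    def __init__(
        self,
        adjacency: dict[int, dict[int, float]],
        leaf_names: dict[int, str],
        supports: dict[Split, float] | None = None,
    ) -> None:
        self.adjacency = adjacency
        self.leaf_names = dict(leaf_names)
        self.supports = dict(supports) if supports else {}
        for u, nbrs in adjacency.items():
            for v, w in nbrs.items():
                if adjacency.get(v, {}).get(u) != w:
                    raise ValidationError(
                        f"adjacency not symmetric on edge ({u}, {v})"
                    )
                if w < 0:
                    raise ValidationError(f"negative branch length on ({u}, {v})")
        names = list(self.leaf_names.values())
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf labels")
        for node, name in self.leaf_names.items():
            if len(adjacency.get(node, {})) != 1:
                raise ValidationError(f"leaf {name!r} does not have degree 1")

    # -- basic structure --------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaves(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def internal_nodes(self) -> list[int]:
        return [n for n in self.adjacency if n not in self.leaf_names]

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels reachable from ``v`` when the edge (u, v) is cut."""
        out: set[str] = set()
        stack = [(u, v)]
        while stack:
            parent, node = stack.pop()
            if node in self.leaf_names:
                out.add(self.leaf_names[node])
            for nbr in self.adjacency[node]:
                if nbr != parent:
                    stack.append((node, nbr))
        return out

    def canonical_split(self, side: set[str]) -> Split:
        all_leaves = set(self.leaf_names.values())
        if not side <= all_leaves:
            raise ValidationError("split side contains unknown leaves")
        if min(all_leaves) in side:
            side = all_leaves - side
        return frozenset(side)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        seen = set()
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v, w

    def splits(self, include_trivial: bool = False) -> dict[Split, tuple[int, int]]:
        """Canonical bipartitions, mapped to one defining edge.

        Non-trivial splits (both sides >= 2 leaves) are the unit of bootstrap
        support accounting; trivial leaf splits are included only on request.
        """
        n = self.n_leaves
        out: dict[Split, tuple[int, int]] = {}
        for u, v, _ in self.edges():
            side = self._side_leaves(u, v)
            if not include_trivial and not (2 <= len(side) <= n - 2):
                continue
            out[self.canonical_split(side)] = (u, v)
        return out

    def has_split(self, side: set[str]) -> bool:
        return self.canonical_split(set(side)) in self.splits()

    def support_of(self, side: set[str]) -> float | None:
        return self.supports.get(self.canonical_split(set(side)))

    # -- metrics ----------------------------------------------------------
    def path_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
        out: dict[tuple[str, str], float] = {}
        for start, name in self.leaf_names.items():
            dist = {start: 0.0}
            stack = [start]
            while stack:
                node = stack.pop()
                for nbr, w in self.adjacency[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + w
                        stack.append(nbr)
            for other, oname in self.leaf_names.items():
                if oname > name:
                    out[(name, oname)] = dist[other]
        return out

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        """Standard Newick; supports become integer internal-node labels."""
        if self.n_leaves < 2:
            raise ValidationError("cannot serialize a tree with fewer than 2 leaves")
        if self.n_leaves == 2:
            a, b = sorted(self.leaf_names.values())
            ((_, _, w),) = list(self.edges())
            return f"({_quote(a)}:{w:.6f},{_quote(b)}:0.000000);"
        # root the display at the internal node next to the smallest leaf
        min_leaf = min(self.leaf_names, key=lambda n: self.leaf_names[n])
        root = next(iter(self.adjacency[min_leaf]))
        return self._render(None, root) + ";"

    def _render(self, parent: int | None, node: int) -> str:
        if node in self.leaf_names:
            length = self.adjacency[node][parent]
            return f"{_quote(self.leaf_names[node])}:{length:.6f}"
        children = [n for n in self.adjacency[node] if n != parent]
        children.sort(key=lambda c: min(self._side_leaves(node, c)))
        inner = ",".join(self._render(node, c) for c in children)
        if parent is None:
            return f"({inner})"
        label = ""
        support = self.support_of(self._side_leaves(parent, node))
        if support is not None:
            label = str(round_half_up(support))
        length = self.adjacency[node][parent]
        return f"({inner}){label}:{length:.6f}"


def _quote(name: str) -> str:
    if any(c in name for c in " ,():;[]'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def random_additive_tree(rng, n_leaves: int,
                         length_range: tuple[float, float] = (0.05, 1.0)
                         ) -> SupportTree:
    """Random unrooted binary tree with uniform branch lengths.

    Built by sequential random leaf attachment.  Its leaf-to-leaf path
    distances form an additive matrix, which makes it the independent
    oracle for distance-based tree reconstruction: any consistent method
    must reproduce the generating topology and path lengths exactly.
    """
    if n_leaves < 3:
        raise ValidationError("need >= 3 leaves")
    lo, hi = length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    adjacency: dict[int, dict[int, float]] = {0: {}, 1: {}, 2: {}, 3: {}}
    for leaf in (0, 1, 2):
        w = bl()
        adjacency[leaf][3] = w
        adjacency[3][leaf] = w
    leaves = {0: "L0", 1: "L1", 2: "L2"}
    next_id = 4
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u, nb in adjacency.items() for v in nb if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adjacency[u][v]
        mid, new_leaf = next_id, next_id + 1
        next_id += 2
        split = float(rng.uniform(0.2, 0.8)) * w
        del adjacency[u][v]
        del adjacency[v][u]
        adjacency.setdefault(mid, {})
        adjacency[u][mid] = adjacency[mid][u] = split
        adjacency[v][mid] = adjacency[mid][v] = w - split
        adjacency[new_leaf] = {}
        adjacency[new_leaf][mid] = adjacency[mid][new_leaf] = bl()
        leaves[new_leaf] = f"L{leaf}"
    return SupportTree(adjacency, leaves)


def write_newick(tree: SupportTree, path) -> None:
    """Serialize ``tree`` to ``path`` in the package's Newick dialect."""
    text = tree.to_newick() + "\n"
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise ValidationError(f"cannot write Newick file {path}: {exc}") from exc
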