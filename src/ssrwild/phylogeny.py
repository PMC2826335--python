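"""Nei-Li distances, neighbor-joining, and bootstrap bipartition support.

The distance between two 0/1 band profiles is the complement of the Dice
similarity,

    D(x, y) = 1 - 2a / (2a + b + c),

with ``a`` the bands shared, ``b`` the bands unique to ``x`` and ``c`` the
bands unique to ``y``.  Jointly absent bands never contribute — the natural
restriction for dominant markers, where absence of a band carries no
information about shared ancestry.  The coefficient is undefined when both
profiles are empty.

Trees are built with the Studier-Keppler formulation of neighbor joining and
supports are estimated by resampling allele characters (or whole markers)
with replacement.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ValidationError
from .model import (
    AlleleMatrix,
    DistanceMatrix,
    SECTIONS,
    Taxonomy,
)
from .tree import SupportTree

logger = logging.getLogger(__name__)

#: Maximum redraws of a bootstrap replicate whose resampled characters leave
#: some accession with an all-absent profile (distance undefined).
MAX_BOOTSTRAP_REDRAWS = 100


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nei_li_distance(x, y) -> float:
    """Nei-Li (Dice-complement) distance between two binary profiles."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValidationError(
            f"profiles must be equal-length 1-D vectors, got shapes "
            f"{x.shape} and {y.shape}"
        )
    if x.size == 0:
        raise ValidationError("profiles must have length >= 1")
    a = int(np.count_nonzero(x & y))
    b = int(np.count_nonzero(x & ~y))
    c = int(np.count_nonzero(~x & y))
    denom = 2 * a + b + c
    if denom == 0:
        raise ValidationError(
            "Nei-Li distance undefined: both profiles are all-absent"
        )
    return 1.0 - (2.0 * a) / denom


def _pairwise_nei_li(cells: np.ndarray, labels: list[str]) -> np.ndarray:
    """All-pairs Nei-Li distances over the columns of a boolean matrix."""
    m = np.asarray(cells, dtype=bool)
    counts = m.sum(axis=0).astype(np.int64)
    if np.any(counts == 0):
        i = int(np.flatnonzero(counts == 0)[0])
        j = 0 if i != 0 else min(1, len(labels) - 1)
        raise ValidationError(
            f"Nei-Li distance undefined for pair ({labels[i]!r}, "
            f"{labels[j]!r}): accession {labels[i]!r} has an all-absent profile"
        )
    a = m.T.astype(np.int64) @ m.astype(np.int64)
    denom = counts[:, None] + counts[None, :]
    d = 1.0 - (2.0 * a) / denom
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(
    mat: AlleleMatrix,
    grouping: str | None = None,
    taxonomy: Taxonomy | None = None,
) -> DistanceMatrix:
    """Pairwise Nei-Li distances among accessions, or section-group means.

    With ``grouping="section"`` the entry for two sections is the arithmetic
    mean of all inter-section accession-pair distances (unweighted average
    linkage), the construction used for section-level dendrograms.
    """
    d = _pairwise_nei_li(mat.cells, mat.accessions)
    if grouping is None:
        if len(mat.accessions) < 2:
            raise ValidationError("need >= 2 accessions for a distance matrix")
        return DistanceMatrix(mat.accessions, d)
    if grouping != "section":
        raise ValidationError(
            f"unsupported grouping {grouping!r}; expected None or 'section'"
        )
    if taxonomy is None:
        raise ValidationError("section grouping requires a taxonomy")
    cols: dict[str, list[int]] = {}
    for j, acc in enumerate(mat.accessions):
        cols.setdefault(taxonomy[acc].section, []).append(j)
    labels = [s for s in SECTIONS if s in cols]
    if len(labels) < 2:
        raise ValidationError("need >= 2 sections after grouping")
    n = len(labels)
    g = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            block = d[np.ix_(cols[labels[i]], cols[labels[j]])]
            g[i, j] = g[j, i] = float(block.mean())
    return DistanceMatrix(labels, g)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> SupportTree:
    """Studier-Keppler neighbor joining on a distance matrix.

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - R_i - R_j`` is
    joined; ties go to the smallest (row, column) position pair, scanning the
    upper triangle row-major, so the result is deterministic.  Negative
    branch lengths (possible on non-additive input) are clamped to zero and
    the raw values logged.

    Labels at exact distance zero (identical band profiles under the Nei-Li
    coefficient) are indistinguishable, and the Q criterion can otherwise
    order them arbitrarily relative to equally similar neighbors; they are
    collapsed to one representative before joining and re-expanded as
    zero-length cherries afterwards, so identical accessions always sit
    together regardless of resampling.
    """
    n = len(D.labels)
    if n < 3:
        raise ValidationError(f"neighbor joining needs >= 3 labels, got {n}")
    reps: list[int] = []
    members: dict[int, list[int]] = {}
    for i in range(n):
        for r in reps:
            if D.values[i, r] == 0.0:
                members[r].append(i)
                break
        else:
            reps.append(i)
            members[i] = [i]
    if len(reps) < n:
        groups = {
            D.labels[r]: sorted(D.labels[m] for m in members[r]) for r in reps
        }
        if len(reps) == 1:
            return _zero_caterpillar(sorted(D.labels))
        if len(reps) == 2:
            a, b = reps
            w = float(D.values[a, b])
            base = SupportTree(
                {0: {1: w}, 1: {0: w}},
                {0: D.labels[a], 1: D.labels[b]},
            )
        else:
            sub = DistanceMatrix(
                [D.labels[r] for r in reps],
                D.values[np.ix_(reps, reps)],
            )
            base = _nj_core(sub)
        return _expand_identical(base, groups)
    return _nj_core(D)


def _zero_caterpillar(labels: list[str]) -> SupportTree:
    """Pectinate tree with all branch lengths zero (all labels identical)."""
    n = len(labels)
    adj: dict[int, dict[int, float]] = {}
    leaf_names = {i: lab for i, lab in enumerate(labels)}

    def add(u: int, v: int) -> None:
        adj.setdefault(u, {})[v] = 0.0
        adj.setdefault(v, {})[u] = 0.0

    hubs = [n + i for i in range(n - 2)]
    add(0, hubs[0])
    add(1, hubs[0])
    for k in range(1, n - 2):
        add(hubs[k - 1], hubs[k])
        add(k + 1, hubs[k])
    add(n - 1, hubs[-1])
    return SupportTree(adj, leaf_names)


def _expand_identical(tree: SupportTree,
                      groups: dict[str, list[str]]) -> SupportTree:
    """Replace each representative leaf by a zero-length cherry/chain of its
    identical-profile members (sorted, so expansion is deterministic)."""
    adj = {u: dict(nb) for u, nb in tree.adjacency.items()}
    leaf_names = dict(tree.leaf_names)
    name_to_node = {nm: nd for nd, nm in leaf_names.items()}
    next_id = max(adj) + 1

    def attach_leaf(cur: int, lab: str) -> None:
        nonlocal next_id
        leaf = next_id
        next_id += 1
        adj.setdefault(leaf, {})[cur] = 0.0
        adj[cur][leaf] = 0.0
        leaf_names[leaf] = lab

    for rep, labels in groups.items():
        if len(labels) == 1:
            continue
        v = name_to_node[rep]
        del leaf_names[v]  # v becomes the internal anchor of the chain
        items = sorted(labels)
        cur = v
        while len(items) > 2:
            attach_leaf(cur, items.pop())
            inner = next_id
            next_id += 1
            adj.setdefault(inner, {})[cur] = 0.0
            adj[cur][inner] = 0.0
            cur = inner
        for lab in items:
            attach_leaf(cur, lab)
    return SupportTree(adj, leaf_names)


def _nj_core(D: DistanceMatrix) -> SupportTree:
    n = len(D.labels)
    d = D.values.astype(float).copy()

    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = {i: lab for i, lab in enumerate(D.labels)}
    active = list(range(n))  # node ids for current rows of d
    next_id = n

    def add_edge(u: int, v: int, w: float) -> None:
        if w < 0:
            logger.debug("clamping negative NJ branch length %.3g on (%d, %d)",
                         w, u, v)
            w = 0.0
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu, ju = np.triu_indices(m, 1)
        k = int(np.argmin(q[iu, ju]))  # first minimum = smallest (i, j)
        i, j = int(iu[k]), int(ju[k])
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        add_edge(u, active[i], li)
        add_edge(u, active[j], lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [t for t in range(m) if t not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        d = np.hstack([d, last[:, None]])
        active = [active[t] for t in keep] + [u]

    # terminal star over the last three nodes
    (a, b, c) = active
    hub = next_id
    add_edge(hub, a, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    add_edge(hub, b, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    add_edge(hub, c, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    return SupportTree(adjacency, leaf_names)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _zero_distance_groups(D: DistanceMatrix) -> list[frozenset]:
    """Equivalence classes of labels at exact distance zero, size >= 3.

    Members of such a class are indistinguishable in the (resampled) data,
    so their internal arrangement is arbitrary: any split nested inside the
    class is counted as supported by that replicate.  Pairs need no special
    treatment — the zero-collapse in :func:`neighbor_joining` already keeps
    them as cherries.
    """
    n = len(D.labels)
    seen: list[list[int]] = []
    for i in range(n):
        for group in seen:
            if D.values[i, group[0]] == 0.0:
                group.append(i)
                break
        else:
            seen.append([i])
    return [
        frozenset(D.labels[i] for i in g) for g in seen if len(g) >= 3
    ]


def _replicate_indices(rng: np.random.Generator, mat: AlleleMatrix,
                       unit: str) -> np.ndarray:
    n_rows = len(mat.alleles)
    if unit == "allele":
        return rng.integers(0, n_rows, size=n_rows)
    if unit == "marker":
        rows = mat.marker_row_indices()
        marker_ids = list(rows)
        picks = rng.integers(0, len(marker_ids), size=len(marker_ids))
        return np.concatenate([np.asarray(rows[marker_ids[p]]) for p in picks])
    raise ValidationError(f"unknown bootstrap unit {unit!r}")


def bootstrap_support(
    mat: AlleleMatrix,
    n_reps: int,
    seed: int,
    grouping: str | None = None,
    taxonomy: Taxonomy | None = None,
    unit: str = "allele",
) -> SupportTree:
    """NJ tree with bootstrap bipartition supports.

    Characters (allele rows, or whole markers with ``unit="marker"``) are
    resampled with replacement ``n_reps`` times; the support of each
    non-trivial bipartition of the full-data tree is the percentage of
    replicate trees containing it.  A replicate that leaves any accession
    with an all-absent profile is redrawn (at most
    :data:`MAX_BOOTSTRAP_REDRAWS` times).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    full = neighbor_joining(distance_matrix(mat, grouping, taxonomy))
    targets = list(full.splits(include_trivial=False))
    counts = dict.fromkeys(targets, 0)

    sec_cols: dict[str, list[int]] | None = None
    if grouping == "section":
        assert taxonomy is not None  # checked in distance_matrix
        sec_cols = {}
        for j, acc in enumerate(mat.accessions):
            sec_cols.setdefault(taxonomy[acc].section, []).append(j)

    rng = np.random.default_rng(int(seed))
    for _ in range(n_reps):
        for attempt in range(MAX_BOOTSTRAP_REDRAWS + 1):
            idx = _replicate_indices(rng, mat, unit)
            cells = mat.cells[idx]
            if cells.any(axis=0).all():
                break
            logger.info("bootstrap replicate left an all-absent accession; "
                        "redrawing (attempt %d)", attempt + 1)
        else:
            raise ValidationError(
                f"could not draw a valid bootstrap replicate in "
                f"{MAX_BOOTSTRAP_REDRAWS} attempts"
            )
        d = _pairwise_nei_li(cells, mat.accessions)
        if sec_cols is None:
            rep_D = DistanceMatrix(mat.accessions, d)
        else:
            labels = [s for s in SECTIONS if s in sec_cols]
            g = np.zeros((len(labels), len(labels)))
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    block = d[np.ix_(sec_cols[labels[i]], sec_cols[labels[j]])]
                    g[i, j] = g[j, i] = float(block.mean())
            rep_D = DistanceMatrix(labels, g)
        rep_splits = neighbor_joining(rep_D).splits()
        zero_groups = _zero_distance_groups(rep_D)
        for s in targets:
            if s in rep_splits or any(s <= g for g in zero_groups):
                counts[s] += 1

    full.supports = {s: 100.0 * counts[s] / n_reps for s in targets}
    return full


# ---------------------------------------------------------------------------
# taxon concordance
# ---------------------------------------------------------------------------

def tree_taxon_concordance(
    tree: SupportTree, taxonomy: Taxonomy, level: str
) -> float:
    """Fraction of multi-accession taxa forming a bipartition side.

    A taxon (species, section or genome class) with >= 2 leaves is counted
    concordant when its leaf set is one side of some edge-induced split of
    the unrooted tree — the unrooted analogue of monophyly.  Taxa spanning
    the entire leaf set are trivially concordant.
    """
    if level not in ("species", "section", "genome"):
        raise ValidationError(
            f"level must be species, section or genome, got {level!r}"
        )
    leaves = set(tree.leaf_names.values())
    for leaf in leaves:
        if leaf not in taxonomy:
            raise ValidationError(f"tree leaf {leaf!r} not in taxonomy")
    groups: dict[str, set[str]] = {}
    for leaf in leaves:
        groups.setdefault(getattr(taxonomy[leaf], level), set()).add(leaf)
    sides = set(tree.splits(include_trivial=True))
    eligible = {t: g for t, g in groups.items() if len(g) >= 2}
    if not eligible:
        return 1.0
    hits = 0
    for g in eligible.values():
        if g == leaves or tree.canonical_split(g) in sides:
            hits += 1
    return hits / len(eligible)
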