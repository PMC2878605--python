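"""Rooted ultrametric trees and stochastic character maps.

Trees are stored in a flat array form (parent pointers, branch lengths,
postorder) that the likelihood and simulation code consumes directly.  Plain
newick reading/writing is delegated to :mod:`dendropy`; the segment-annotated
SIMMAP-style dialect used for stochastic character maps has its own small
parser because no installed library reads it.

SIMMAP dialect
--------------
Each branch carries, in place of a branch length, an ordered segment list

    ``{state,duration:state,duration:...}``

written **rootward to tipward** (SIMMAP variants disagree on this ordering;
rootward-first is this module's convention).  The branch length is the sum of
the segment durations.  Example, a two-tip tree whose branch to ``A`` starts
in ``rock`` and switches to ``terrestrial`` 0.4 time units below the root::

    (A:{rock,0.4:terrestrial,0.6},B:{rock,1.0});

Zero-duration segments are dropped and adjacent same-state segments merged on
construction, so map invariants hold by construction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

#: Canonical habitat-state order used throughout the package.
HABITAT_STATES: tuple[str, ...] = ("rock", "terrestrial", "semiarboreal", "arboreal")

#: Relative tolerance for the ultrametricity check (× root depth).
ULTRAMETRIC_RTOL = 1e-6

#: Relative tolerance for segment-duration vs branch-length agreement.
SEGMENT_RTOL = 1e-9


class NewickParseError(ValueError):
    """Malformed newick/SIMMAP input; the message names the offending position."""


class TreeValidationError(ValueError):
    """A structural invariant of a tree or stochastic map is violated."""


class Tree:
    """Rooted phylogeny with branch lengths in relative time.

    Nodes are integers ``0..n_nodes-1`` with tips first (``0..n_tips-1``).
    ``parent[root] == -1`` and ``blen[root] == 0``.  Branch lengths are
    nonnegative; zero-length branches (resolved polytomies) are allowed.

    Parameters
    ----------
    parent
        Parent index per node, ``-1`` for the root.
    blen
        Branch length above each node (ignored for the root).
    labels
        Tip labels, one per tip, in tip-index order; must be unique.
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: Sequence[str],
        *,
        check_ultrametric: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = tuple(str(x) for x in labels)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        if len(self.blen) != self.n_nodes:
            raise TreeValidationError("parent and blen arrays differ in length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.blen[self.root] = 0.0
        if len(set(self.labels)) != self.n_tips:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if np.any(self.blen < 0):
            bad = np.flatnonzero(self.blen < 0)
            raise TreeValidationError(f"negative branch lengths at nodes {bad.tolist()}")
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v != self.root:
                children[self.parent[v]].append(v)
        self.children = tuple(tuple(c) for c in children)
        for tip in range(self.n_tips):
            if self.children[tip]:
                raise TreeValidationError(f"node {tip} is labelled a tip but has children")
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]
        self._tips_below: tuple[np.ndarray, ...] | None = None
        self.ultrametric = True
        if check_ultrametric:
            d = self.depths()[: self.n_tips]
            depth = float(d.max())
            if depth > 0 and (d.max() - d.min()) > ULTRAMETRIC_RTOL * depth:
                self.ultrametric = False
                warnings.warn(
                    "tree is not ultrametric: tip depth range "
                    f"[{d.min():.6g}, {d.max():.6g}]",
                    stacklevel=2,
                )

    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        seen = 0
        while stack:
            v = stack.pop()
            order.append(v)
            seen += 1
            stack.extend(self.children[v])
        if seen != self.n_nodes:
            raise TreeValidationError("tree contains a cycle or disconnected node")
        return np.asarray(order[::-1], dtype=np.intp)

    # ------------------------------------------------------------------ geometry

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    @property
    def depth(self) -> float:
        """Root depth (maximum root-to-tip distance)."""
        return float(self.depths()[: self.n_tips].max())

    def tips_below(self, node: int) -> np.ndarray:
        """Tip indices descending from (or equal to) ``node``."""
        if self._tips_below is None:
            below: list[np.ndarray | None] = [None] * self.n_nodes
            for v in self.postorder:
                if not self.children[v]:
                    below[v] = np.array([v], dtype=np.intp)
                else:
                    below[v] = np.concatenate([below[c] for c in self.children[v]])
            self._tips_below = tuple(below)  # type: ignore[arg-type]
        return self._tips_below[node]

    def mrca(self, tips: Iterable[int]) -> int:
        """Most recent common ancestor of a set of tip indices."""
        want = set(tips)
        for v in self.postorder:
            if want <= set(self.tips_below(v).tolist()):
                return int(v)
        raise TreeValidationError("tip set not found in tree")

    def is_monophyletic(self, tip_labels: Iterable[str]) -> bool:
        """Whether the labelled tips form an exact clade."""
        idx = [self.labels.index(x) for x in tip_labels]
        return len(self.tips_below(self.mrca(idx))) == len(idx)

    def vcv(self) -> np.ndarray:
        """Phylogenetic covariance matrix: shared root-to-tip path lengths."""
        C = np.zeros((self.n_tips, self.n_tips))
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            tips = self.tips_below(v)
            C[np.ix_(tips, tips)] += self.blen[v]
        return C

    def rescaled(self, depth: float = 1.0) -> "Tree":
        """Copy with branch lengths scaled so the root depth equals ``depth``."""
        cur = self.depth
        if cur <= 0:
            raise TreeValidationError("cannot rescale a tree of zero depth")
        return Tree(self.parent, self.blen * (depth / cur), self.labels)

    # ------------------------------------------------------------------ newick I/O

    def to_newick(self) -> str:
        """Serialize as a single-line newick string with full-precision lengths."""
        parts: dict[int, str] = {}
        for v in self.postorder:
            if not self.children[v]:
                body = _quote_label(self.labels[v])
            else:
                body = "(" + ",".join(parts.pop(c) for c in self.children[v]) + ")"
            if v == self.root:
                parts[v] = body
            else:
                parts[v] = f"{body}:{float(self.blen[v])!r}"
        return parts[self.root] + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Tree {self.n_tips} tips, depth {self.depth:.4g}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;{}[]' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _tree_from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.preorder_node_iter())
    leaves = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    index = {id(nd): i for i, nd in enumerate(leaves)}
    index.update({id(nd): len(leaves) + i for i, nd in enumerate(internals)})
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.intp)
    blen = np.zeros(n)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError(
                    f"branch length missing on edge above {nd.taxon or 'an internal node'}"
                )
            blen[i] = float(nd.edge.length)
    labels = [
        (lf.taxon.label if lf.taxon is not None else "") for lf in leaves
    ]
    if any(lab == "" for lab in labels):
        raise NewickParseError("unlabelled tip in newick input")
    return Tree(parent, blen, labels)


def parse_newick(text: str) -> Tree:
    """Parse a single plain-newick tree.

    Ultrametricity is advisory here: a tree whose tip depths disagree beyond
    tolerance is returned with ``tree.ultrametric == False`` and a warning,
    because posterior tree samples commonly carry rounding slop.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _tree_from_dendropy(dtree)


def read_trees(source: str | io.TextIOBase) -> list[Tree]:
    """Read a multi-tree newick file (one tree per line); path or handle."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    return [parse_newick(line) for line in lines if line.strip()]


def write_trees(trees: Iterable[Tree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Stochastic character maps
# ---------------------------------------------------------------------------


def _normalize_segments(segs: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Drop zero-duration segments and merge adjacent same-state runs."""
    out: list[tuple[str, float]] = []
    for state, dur in segs:
        dur = float(dur)
        if dur < 0:
            raise TreeValidationError(f"negative segment duration {dur} for state {state}")
        if dur == 0.0:
            continue
        if out and out[-1][0] == state:
            out[-1] = (state, out[-1][1] + dur)
        else:
            out.append((state, dur))
    return out


@dataclass
class StochasticMap:
    """A realized history of a discrete character painted onto a tree.

    ``segments[v]`` is the ordered (rootward → tipward) list of
    ``(state, duration)`` pairs on the branch above node ``v``; the root has
    no branch and an empty list.  Segment durations on each branch sum to the
    branch length, and the rootward state of every branch matches the tipward
    state of its parent branch (children of the root all start in the root
    state).
    """

    tree: Tree
    segments: list[list[tuple[str, float]]]
    validate: bool = True
    _occupancy: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.segments = [_normalize_segments(s) for s in self.segments]
        if self.validate:
            self._validate()

    def _validate(self) -> None:
        t = self.tree
        if len(self.segments) != t.n_nodes:
            raise TreeValidationError("one segment list per node required")
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            if not self.segments[v] and t.blen[v] > 0:
                raise TreeValidationError(f"branch above node {v} has no segments")
            total = sum(d for _, d in self.segments[v])
            ref = max(t.blen[v], t.depth)
            if abs(total - t.blen[v]) > SEGMENT_RTOL * max(ref, 1.0):
                raise TreeValidationError(
                    f"segment durations on branch above node {v} sum to {total!r}, "
                    f"branch length is {t.blen[v]!r}"
                )
        for v in range(t.n_nodes):
            if v == t.root or t.parent[v] == t.root:
                continue
            p = int(t.parent[v])
            if self.segments[v] and self.segments[p]:
                if self.segments[v][0][0] != self.segments[p][-1][0]:
                    raise TreeValidationError(
                        f"state mismatch at node {p}: branch above node {v} starts in "
                        f"{self.segments[v][0][0]!r} but parent branch ends in "
                        f"{self.segments[p][-1][0]!r}"
                    )

    # ------------------------------------------------------------------ queries

    @property
    def states(self) -> tuple[str, ...]:
        """States present on the map, in canonical order where applicable."""
        seen = {s for segs in self.segments for s, _ in segs}
        ordered = [s for s in HABITAT_STATES if s in seen]
        ordered += sorted(seen - set(ordered))
        return tuple(ordered)

    @property
    def root_state(self) -> str:
        for c in self.tree.children[self.tree.root]:
            if self.segments[c]:
                return self.segments[c][0][0]
        raise TreeValidationError("map has no segments")

    def tip_states(self) -> dict[str, str]:
        """Observed state at each tip (the tipward end of its branch)."""
        return {
            self.tree.labels[tip]: self.node_state(tip)
            for tip in range(self.tree.n_tips)
        }

    def node_state(self, v: int) -> str:
        """State at the tipward end of the branch above ``v`` (root: root state)."""
        if v == self.tree.root:
            return self.root_state
        while not self.segments[v]:
            v = int(self.tree.parent[v])
            if v == self.tree.root:
                return self.root_state
        return self.segments[v][-1][0]

    def n_transitions(self) -> int:
        return sum(max(len(s) - 1, 0) for s in self.segments)

    def occupancy(self, states: Sequence[str] | None = None) -> np.ndarray:
        """Per-branch time in each state: array ``(n_states, n_nodes)``."""
        states = tuple(states) if states is not None else self.states
        occ = np.zeros((len(states), self.tree.n_nodes))
        idx = {s: k for k, s in enumerate(states)}
        for v, segs in enumerate(self.segments):
            for s, d in segs:
                if s in idx:
                    occ[idx[s], v] += d
        return occ

    def shared_path_times(self, states: Sequence[str] | None = None) -> dict[str, np.ndarray]:
        """Per-state matrices of shared root-to-tip time spent in each state.

        Entry ``(i, j)`` of the matrix for state ``k`` is the total duration
        spent in ``k`` on branches common to the root-to-``i`` and
        root-to-``j`` paths.  Summed over states these matrices reproduce the
        tree's phylogenetic covariance matrix exactly.
        """
        states = tuple(states) if states is not None else self.states
        t = self.tree
        occ = self.occupancy(states)
        out = {s: np.zeros((t.n_tips, t.n_tips)) for s in states}
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            tips = t.tips_below(v)
            block = np.ix_(tips, tips)
            for k, s in enumerate(states):
                if occ[k, v]:
                    out[s][block] += occ[k, v]
        return out

    def shared_path_stack(self, states: Sequence[str]) -> np.ndarray:
        """:meth:`shared_path_times` as a ``(n_states, n_tips, n_tips)`` array."""
        mats = self.shared_path_times(states)
        return np.stack([mats[s] for s in states])

    # ------------------------------------------------------------------ I/O

    def to_simmap(self) -> str:
        """Serialize in the package's SIMMAP dialect (rootward→tipward)."""
        t = self.tree
        parts: dict[int, str] = {}
        for v in t.postorder:
            if not t.children[v]:
                body = _quote_label(t.labels[v])
            else:
                body = "(" + ",".join(parts.pop(c) for c in t.children[v]) + ")"
            if v == t.root:
                parts[v] = body
            else:
                segs = self.segments[v] or [(self.node_state(v), 0.0)]
                ann = ":".join(f"{s},{float(d)!r}" for s, d in segs)
                parts[v] = f"{body}:{{{ann}}}"
        return parts[t.root] + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"<StochasticMap {self.tree.n_tips} tips, "
            f"{self.n_transitions()} transitions, root {self.root_state!r}>"
        )


class _SimmapParser:
    """Recursive-descent parser for the SIMMAP dialect documented above."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickParseError:
        return NewickParseError(f"{msg} at character offset {self.pos}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def expect(self, ch: str) -> None:
        self.skip_ws()
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                ch = self.text[self.pos]
                self.pos += 1
                if ch == "'":
                    if self.peek() == "'":
                        self.pos += 1
                        out.append("'")
                    else:
                        break
                else:
                    out.append(ch)
            return "".join(out)
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;{}[] \t\n":
            self.pos += 1
        if self.pos == start:
            raise self.error("expected a label")
        return self.text[start : self.pos]

    def number(self) -> float:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in ",:;(){}[] \t\n":
            self.pos += 1
        try:
            return float(self.text[start : self.pos])
        except ValueError:
            raise self.error(f"invalid number {self.text[start:self.pos]!r}") from None

    def segment_list(self) -> list[tuple[str, float]]:
        self.expect(":")
        self.expect("{")
        segs = []
        while True:
            state = self.label()
            self.expect(",")
            segs.append((state, self.number()))
            self.skip_ws()
            if self.peek() == ":":
                self.pos += 1
                continue
            self.expect("}")
            break
        return segs

    def parse(self) -> StochasticMap:
        labels: list[str] = []
        # node records as (children, segments); tips reference labels by index
        parents: list[int] = []
        seglists: list[list[tuple[str, float]]] = []
        is_tip: list[bool] = []

        def subtree(parent: int) -> int:
            self.skip_ws()
            me = len(parents)
            parents.append(parent)
            seglists.append([])
            if self.peek() == "(":
                is_tip.append(False)
                self.pos += 1
                while True:
                    subtree(me)
                    self.skip_ws()
                    if self.peek() == ",":
                        self.pos += 1
                        continue
                    self.expect(")")
                    break
            else:
                is_tip.append(True)
                labels.append(self.label())
            if parent >= 0:
                seglists[me] = self.segment_list()
            return me

        root = subtree(-1)
        self.expect(";")
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        # renumber: tips first in appearance order, then internals
        tip_old = [i for i, t in enumerate(is_tip) if t]
        int_old = [i for i, t in enumerate(is_tip) if not t]
        new = {old: i for i, old in enumerate(tip_old)}
        new.update({old: len(tip_old) + i for i, old in enumerate(int_old)})
        n = len(parents)
        parent_arr = np.full(n, -1, dtype=np.intp)
        blen = np.zeros(n)
        segs_new: list[list[tuple[str, float]]] = [[] for _ in range(n)]
        for old in range(n):
            i = new[old]
            if parents[old] >= 0:
                parent_arr[i] = new[parents[old]]
            segs_new[i] = seglists[old]
            blen[i] = sum(d for _, d in seglists[old])
        tree = Tree(parent_arr, blen, labels)
        return StochasticMap(tree, segs_new)


def parse_simmap(text: str) -> StochasticMap:
    """Parse one SIMMAP-dialect annotated newick string into a map."""
    return _SimmapParser(text).parse()


def read_maps(source: str | io.TextIOBase) -> list[StochasticMap]:
    """Read a multi-map SIMMAP file, one map per line."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    return [parse_simmap(line) for line in lines if line.strip()]


def write_maps(maps: Iterable[StochasticMap], path: str) -> None:
    with open(path, "w") as fh:
        for m in maps:
            fh.write(m.to_simmap() + "\n")


def habitat_from_csv(source: str | io.TextIOBase) -> dict[str, str]:
    """Read a species→habitat CSV with columns ``species,habitat``."""
    import pandas as pd

    df = pd.read_csv(source)
    missing = {"species", "habitat"} - set(df.columns)
    if missing:
        raise ValueError(f"habitat CSV lacks columns: {sorted(missing)}")
    bad = set(df["habitat"]) - set(HABITAT_STATES)
    if bad:
        raise ValueError(
            f"unknown habitat states {sorted(bad)}; expected one of {HABITAT_STATES}"
        )
    return dict(zip(df["species"].astype(str), df["habitat"]))
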