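"""Fold topology strings for three-layer alpha/beta/alpha architectures.

A fold is abstracted as the path of the chain through a lattice of secondary
structure elements (SSEs) arranged in three layers: a central beta-sheet layer
``B`` flanked by two helix layers ``A`` and ``C``.  Each SSE is encoded by a
token ``<dir><layer><pos>``, e.g. ``+B+0``: a direction (``+``/``-`` along the
common strand axis), a layer letter, and a signed integer slot within the
layer.  The tokens are listed in chain order (N to C).

Canonical form fixes the labelling gauge:

* the first SSE to enter each layer takes position 0;
* the first strand in the chain takes the ``+`` direction;
* the layer of the first helix in the chain is labelled ``A``;
* the residual mirror ambiguity of the lateral axis is resolved by requiring a
  right-handed frame (lateral = strand-direction x layer-normal), which at the
  string level amounts to selecting among the four proper 180-degree rotations
  of the architecture; degenerate cases (no strands, or no helices) are broken
  lexicographically on the serialized string.

Sheet positions must form a contiguous integer range (a sheet has no holes);
helix layers may contain unoccupied intermediate slots.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TopologyError",
    "SSEDescriptor",
    "TopologyString",
    "parse_topology",
    "format_topology",
    "canonicalize",
    "same_fold",
    "edit_distance",
    "classify_central_swap",
    "swap_sheet_positions",
    "read_topology_file",
]

LAYERS = ("A", "B", "C")

# internal representation: tuple of (layer: str, position: int, direction: +1/-1)
Element = tuple[str, int, int]


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology strings."""


@dataclass(frozen=True)
class SSEDescriptor:
    """One secondary structure element: layer letter, lattice slot, direction."""

    layer: str
    position: int
    direction: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise TopologyError(f"invalid layer {self.layer!r}")
        if self.direction not in (1, -1):
            raise TopologyError(f"direction must be +1 or -1, got {self.direction!r}")
        if not isinstance(self.position, int):
            raise TopologyError(f"position must be an integer, got {self.position!r}")

    @property
    def kind(self) -> str:
        """``strand`` for layer B, ``helix`` for layers A and C."""
        return "strand" if self.layer == "B" else "helix"

    @property
    def is_strand(self) -> bool:
        return self.layer == "B"

    def _tuple(self) -> Element:
        return (self.layer, self.position, self.direction)

    def __str__(self) -> str:
        return _format_token(self._tuple())


@dataclass(frozen=True)
class TopologyString:
    """An ordered (N to C) sequence of SSE descriptors encoding a fold."""

    elements: tuple[SSEDescriptor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.elements:
            raise TopologyError("empty topology")
        _validate(self._tuples())

    def _tuples(self) -> tuple[Element, ...]:
        return tuple(e._tuple() for e in self.elements)

    @classmethod
    def _from_tuples(cls, elems: Iterable[Element]) -> "TopologyString":
        return cls(tuple(SSEDescriptor(l, p, d) for l, p, d in elems))

    @classmethod
    def parse(cls, text: str) -> "TopologyString":
        return parse_topology(text)

    def canonical(self) -> "TopologyString":
        return canonicalize(self)

    @property
    def is_canonical(self) -> bool:
        return self._tuples() == _canonical_tuples(self._tuples())

    @property
    def n_strands(self) -> int:
        return sum(1 for e in self.elements if e.is_strand)

    @property
    def n_helices(self) -> int:
        return len(self.elements) - self.n_strands

    def strands(self) -> tuple[SSEDescriptor, ...]:
        return tuple(e for e in self.elements if e.is_strand)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[SSEDescriptor]:
        return iter(self.elements)

    def __str__(self) -> str:
        return format_topology(self)


# ---------------------------------------------------------------------------
# parsing / formatting

_TOKEN_RE = re.compile(r"^([+-])([A-Za-z])([+-]\d+)$")


def _format_token(elem: Element) -> str:
    layer, pos, d = elem
    return f"{'+' if d > 0 else '-'}{layer}{'+' if pos >= 0 else '-'}{abs(pos)}"


def parse_topology(text: str) -> TopologyString:
    """Parse a whitespace-separated token string such as ``"+B+0 -B+1 +A+0"``.

    Unicode minus signs are accepted and normalized to ASCII ``-``.
    """
    text = text.replace("−", "-").strip()
    if not text:
        raise TopologyError("empty topology")
    elems: list[Element] = []
    for token in text.split():
        m = _TOKEN_RE.match(token)
        if m is None:
            raise TopologyError(f"malformed topology token {token!r}")
        sign, layer, pos = m.groups()
        if layer not in LAYERS:
            raise TopologyError(f"invalid layer letter in token {token!r}")
        elems.append((layer, int(pos), 1 if sign == "+" else -1))
    return TopologyString._from_tuples(elems)


def format_topology(ts: TopologyString) -> str:
    """Serialize a topology string with single-space separation and explicit signs."""
    return " ".join(_format_token(e) for e in ts._tuples())


# ---------------------------------------------------------------------------
# validation and canonical form

def _validate(elems: Sequence[Element]) -> None:
    """Check layer letters, per-layer slot uniqueness and sheet contiguity."""
    per_layer: dict[str, list[int]] = {}
    for layer, pos, d in elems:
        if layer not in LAYERS:
            raise TopologyError(f"invalid layer {layer!r}")
        per_layer.setdefault(layer, []).append(pos)
    for layer, positions in per_layer.items():
        if len(set(positions)) != len(positions):
            raise TopologyError(f"duplicate position in layer {layer}")
    b = sorted(per_layer.get("B", []))
    if b and b[-1] - b[0] != len(b) - 1:
        raise TopologyError("sheet gap")


# The four proper 180-degree rotations that map the three-layer architecture
# onto itself, as (flip all directions, swap A/C, negate lateral positions).
# 180 about the layer normal flips directions and negates positions; 180 about
# the strand axis swaps the helix layers and negates positions; 180 about the
# lateral axis flips directions and swaps helix layers.
_OPS: tuple[tuple[bool, bool, bool], ...] = (
    (False, False, False),
    (True, False, True),
    (False, True, True),
    (True, True, False),
)


def _apply_op(op: tuple[bool, bool, bool], elems: Sequence[Element]) -> tuple[Element, ...]:
    flip, swap, neg = op
    out = []
    for layer, pos, d in elems:
        if swap and layer != "B":
            layer = "A" if layer == "C" else "C"
        out.append((layer, -pos if neg else pos, -d if flip else d))
    return tuple(out)


def _zero_offsets(elems: Sequence[Element]) -> tuple[Element, ...]:
    first: dict[str, int] = {}
    for layer, pos, _ in elems:
        first.setdefault(layer, pos)
    return tuple((l, p - first[l], d) for l, p, d in elems)


def _canonical_tuples(elems: Sequence[Element]) -> tuple[Element, ...]:
    _validate(elems)
    candidates = []
    for op in _OPS:
        t = _zero_offsets(_apply_op(op, elems))
        strands = [e for e in t if e[0] == "B"]
        if strands and strands[0][2] != 1:
            continue
        helices = [e for e in t if e[0] != "B"]
        if helices and helices[0][0] != "A":
            continue
        candidates.append(t)
    # with strands and helices present exactly one candidate survives; the
    # degenerate all-strand / all-helix cases are broken lexicographically
    return min(candidates, key=lambda t: tuple(_format_token(e) for e in t))


def canonicalize(ts: TopologyString) -> TopologyString:
    """Return the canonical relabelling of *ts* (idempotent)."""
    return TopologyString._from_tuples(_canonical_tuples(ts._tuples()))


def same_fold(a: TopologyString, b: TopologyString) -> bool:
    """True iff the canonical forms are element-wise identical."""
    return _canonical_tuples(a._tuples()) == _canonical_tuples(b._tuples())


# ---------------------------------------------------------------------------
# topological edit distance

def _renumber_sheet(elems: Sequence[Element]) -> tuple[Element, ...]:
    """Close any gap in layer B by renumbering slots to consecutive ranks."""
    b_positions = sorted(p for l, p, _ in elems if l == "B")
    rank = {p: i for i, p in enumerate(b_positions)}
    return tuple((l, rank[p] if l == "B" else p, d) for l, p, d in elems)


def _neighbors(
    state: tuple[Element, ...], max_len: int, helix_span: int
) -> set[tuple[Element, ...]]:
    """Canonical states one unit edit away from *state*.

    Unit edits: (i) exchange the slots of two SSEs in the same layer;
    (ii) flip one SSE's direction; (iii) delete or insert one SSE (sheet
    slots renumbered to stay contiguous); (iv) slide one helix to an
    unoccupied slot in its layer.  Intermediate states are bounded to at
    most *max_len* elements with helix slots within ``[-helix_span,
    helix_span]`` of the occupied range so that the search space is finite.
    """
    out: set[tuple[Element, ...]] = set()

    def admit(raw: Sequence[Element]) -> None:
        try:
            c = _canonical_tuples(raw)
        except TopologyError:
            return
        if len(c) > max_len:
            return
        if any(abs(p) > helix_span for l, p, _ in c if l != "B"):
            return
        if c != state:
            out.add(c)

    n = len(state)
    # (i) in-layer slot exchange
    for i in range(n):
        for j in range(i + 1, n):
            if state[i][0] == state[j][0]:
                lst = list(state)
                li, pi, di = lst[i]
                lj, pj, dj = lst[j]
                lst[i] = (li, pj, di)
                lst[j] = (lj, pi, dj)
                admit(lst)
    # (ii) direction flip
    for i in range(n):
        lst = list(state)
        l, p, d = lst[i]
        lst[i] = (l, p, -d)
        admit(lst)
    # (iii) deletion
    if n > 1:
        for i in range(n):
            lst = [e for k, e in enumerate(state) if k != i]
            admit(_renumber_sheet(lst))
    # (iii) insertion
    if n < max_len:
        b_count = sum(1 for l, _, _ in state if l == "B")
        for chain_idx in range(n + 1):
            for d in (1, -1):
                # new strand at any sheet rank, shifting higher slots up
                for rank in range(b_count + 1):
                    lst = []
                    for l, p, dd in state:
                        if l == "B" and p >= rank:
                            p += 1
                        lst.append((l, p, dd))
                    lst.insert(chain_idx, ("B", rank, d))
                    admit(_renumber_sheet(lst))
                # new helix adjacent to the occupied range of its layer
                for layer in ("A", "C"):
                    occ = sorted(p for l, p, _ in state if l == layer)
                    if occ:
                        slots = [p for p in range(occ[0] - 1, occ[-1] + 2) if p not in occ]
                    else:
                        slots = [0]
                    for p in slots:
                        lst = list(state)
                        lst.insert(chain_idx, (layer, p, d))
                        admit(lst)
    # (iv) helix slide to an unoccupied slot of the same layer
    for i, (l, p, d) in enumerate(state):
        if l == "B":
            continue
        occ = {pp for ll, pp, _ in state if ll == l}
        lo = min(occ) - 1
        hi = max(occ) + 1
        for target in range(lo, hi + 1):
            if target in occ:
                continue
            lst = list(state)
            lst[i] = (l, target, d)
            admit(lst)
    return out


def edit_distance(
    a: TopologyString,
    b: TopologyString,
    *,
    max_len: int | None = None,
    helix_span: int | None = None,
    max_dist: int | None = None,
) -> int | None:
    """Minimal number of unit topology edits transforming *a* into *b*.

    Computed as a shortest path by bidirectional breadth-first search over
    canonical strings.  ``max_dist`` caps the search; ``None`` is returned when
    the distance exceeds it.  The default bounds always admit the trivial
    delete-all/insert-all path, so without a cap the result is a finite
    integer.  Zero iff :func:`same_fold`.
    """
    ca = _canonical_tuples(a._tuples())
    cb = _canonical_tuples(b._tuples())
    if ca == cb:
        return 0
    if max_len is None:
        max_len = max(len(ca), len(cb))
    if helix_span is None:
        spans = [abs(p) for t in (ca, cb) for l, p, _ in t if l != "B"]
        helix_span = max(spans, default=1) + 1
    if max_dist is None:
        max_dist = len(ca) + len(cb)

    front: dict[tuple[Element, ...], int] = {ca: 0}
    back: dict[tuple[Element, ...], int] = {cb: 0}
    f_frontier, b_frontier = {ca}, {cb}
    while f_frontier and b_frontier:
        # expand the smaller frontier
        if len(f_frontier) <= len(b_frontier):
            frontier, dist, other = f_frontier, front, back
        else:
            frontier, dist, other = b_frontier, back, front
        new_frontier: set[tuple[Element, ...]] = set()
        best: int | None = None
        for s in frontier:
            d = dist[s]
            for nb in _neighbors(s, max_len, helix_span):
                if nb in other:
                    total = d + 1 + other[nb]
                    best = total if best is None else min(best, total)
                if nb not in dist:
                    dist[nb] = d + 1
                    new_frontier.add(nb)
        if best is not None:
            return best if best <= max_dist else None
        if f_frontier is frontier:
            f_frontier = new_frontier
        else:
            b_frontier = new_frontier
        min_f = min((front[s] for s in f_frontier), default=max_dist + 1)
        min_b = min((back[s] for s in b_frontier), default=max_dist + 1)
        if min_f + min_b + 1 > max_dist:
            return None
    return None


# ---------------------------------------------------------------------------
# central strand swap taxonomy

#: possible labels for the permutation of the three central sheet positions
SWAP_LABELS = ("none", "2-1-3", "1-3-2", "3-2-1", "other")


@dataclass(frozen=True)
class SwapClass:
    """Permutation class of the three central beta-sheet positions.

    Excluding edge strands, a five-stranded sheet leaves three central
    positions, and a single pairwise exchange can produce only the orders
    2,1,3 (swap of positions 1 and 2), 1,3,2 (swap of 2 and 3) and 3,2,1
    (swap of 1 and 3).  ``none`` means the central ordering is identical,
    ``other`` that the rearrangement is not a single central transposition.
    """

    label: str

    def __post_init__(self) -> None:
        if self.label not in SWAP_LABELS:
            raise TopologyError(f"invalid swap label {self.label!r}")

    @property
    def is_single_transposition(self) -> bool:
        return self.label in ("2-1-3", "1-3-2", "3-2-1")


_PERM_TO_LABEL = {
    (1, 2, 3): "none",
    (2, 1, 3): "2-1-3",
    (1, 3, 2): "1-3-2",
    (3, 2, 1): "3-2-1",
}


def _sheet_ranks(ts: TopologyString) -> list[int]:
    """Sheet rank (0 = leftmost) of each strand in chain order."""
    positions = [e.position for e in ts.strands()]
    lo = min(positions)
    return [p - lo for p in positions]


def classify_central_swap(a: TopologyString, b: TopologyString) -> SwapClass:
    """Classify how *b* reorders the three central sheet positions of *a*.

    Both strings must be canonical with at least five strands; strand k in
    chain order of *a* is matched with strand k of *b*.  For sheets larger
    than five strands the central window is the middle three position ranks.
    """
    a = canonicalize(a)
    b = canonicalize(b)
    ra, rb = _sheet_ranks(a), _sheet_ranks(b)
    if len(ra) < 5 or len(rb) < 5:
        raise TopologyError("sheet too small for central-swap analysis")
    if len(ra) != len(rb):
        return SwapClass("other")
    k = len(ra)
    start = (k - 2) // 2  # first of the middle three ranks; 1 for a 5-strand sheet
    central = [start, start + 1, start + 2]
    # chain-strand indices occupying the central ranks of a, labelled 1..3
    # in a's left-to-right sheet order
    by_rank = {r: i for i, r in enumerate(ra)}
    segs = [by_rank[r] for r in central]  # chain index of label 1, 2, 3
    if sorted(rb[s] for s in segs) != central:
        return SwapClass("other")
    # b's left-to-right order of those same chain segments
    order = tuple(
        lbl + 1
        for _, lbl in sorted((rb[s], lbl) for lbl, s in enumerate(segs))
    )
    return SwapClass(_PERM_TO_LABEL.get(order, "other"))


def swap_sheet_positions(ts: TopologyString, rank_a: int, rank_b: int) -> TopologyString:
    """Exchange the sheet slots of the strands at two sheet ranks.

    Ranks count strands left to right in the sheet (0 = leftmost).  The
    strands keep their chain positions and directions; only their lateral
    slots are exchanged, which is the strand-swap fold change.  Returns the
    canonical form of the variant.
    """
    ts = canonicalize(ts)
    positions = sorted(e.position for e in ts.strands())
    k = len(positions)
    if not (0 <= rank_a < k and 0 <= rank_b < k):
        raise TopologyError(f"sheet ranks must be in [0, {k})")
    pa, pb = positions[rank_a], positions[rank_b]
    out = []
    for e in ts.elements:
        if e.is_strand and e.position == pa:
            out.append(SSEDescriptor(e.layer, pb, e.direction))
        elif e.is_strand and e.position == pb:
            out.append(SSEDescriptor(e.layer, pa, e.direction))
        else:
            out.append(e)
    return canonicalize(TopologyString(tuple(out)))


# ---------------------------------------------------------------------------
# text file interface

def read_topology_file(path) -> list[TopologyString]:
    """Read one topology string per line; ``#`` starts a comment."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(parse_topology(line))
    return out


def write_topology_file(path, strings: Iterable[TopologyString]) -> None:
    with open(path, "w") as fh:
        for ts in strings:
            fh.write(format_topology(ts) + "\n")
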