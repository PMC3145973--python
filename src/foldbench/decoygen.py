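"""Lattice decoy models: fold enumeration, filtering and C-alpha model building.

Folds are enumerated on ideal three-layer lattice frameworks ("forms"): a
central beta-sheet layer flanked by two helix layers, e.g. a 2-5-2 form has
two helix slots above a five-strand sheet above two more helix slots.  The
chain's SSEs are permuted over the lattice slots and directions, and the
resulting topologies are filtered to remove left-handed parallel beta
crossovers and crossing loops, then deduplicated under canonicalization.

Surviving folds are built into ideal-geometry C-alpha traces (helices on a
1.5 A rise / 100 degree twist / 2.3 A radius, strands as 3.4 A-rise zig-zag
traces) joined by seeded pseudo-random self-avoiding loops, and a topology
string can be recovered from coordinates by fitting the three-layer frame.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .topology import (
    Element,
    TopologyError,
    TopologyString,
    _canonical_tuples,
    format_topology,
)

__all__ = [
    "Form",
    "CaModel",
    "BuildError",
    "enumerate_folds",
    "is_right_handed",
    "has_loop_crossing",
    "build_ca_model",
    "extract_topology",
    "read_ca_pdb",
    "write_ca_pdb",
    "assign_sse_from_ca",
]

# ideal local geometry (Angstrom)
CA_BOND = 3.8
STRAND_RISE = 3.4
HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3
# zig-zag half-amplitude making the strand virtual bond exactly CA_BOND
_STRAND_WOBBLE = math.sqrt(CA_BOND**2 - STRAND_RISE**2) / 2.0
CLASH_DIST = 3.0


class BuildError(RuntimeError):
    """Raised when a C-alpha model cannot be constructed."""


@dataclass(frozen=True)
class Form:
    """An ideal lattice framework: slot counts per layer and spacings.

    ``n_a``/``n_c`` are helix slots in the two flanking layers, ``n_b`` strand
    slots in the sheet.  Spacings are representative ideal values: 5 A between
    sheet strands, 10 A between helices in a layer and 10 A between the sheet
    plane and each helix layer; the sheet is flat (untwisted).
    """

    n_a: int
    n_b: int
    n_c: int
    strand_sep: float = 5.0
    helix_sep: float = 10.0
    layer_sep: float = 10.0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_c) < 0:
            raise ValueError("layer sizes must be non-negative")
        if min(self.strand_sep, self.helix_sep, self.layer_sep) <= 0:
            raise ValueError("lattice spacings must be positive")

    @property
    def name(self) -> str:
        return f"{self.n_a}-{self.n_b}-{self.n_c}"

    def slot_center(self, layer: str, position: int) -> np.ndarray:
        """3D axis anchor of a lattice slot (sheet plane at z = 0, layer A above)."""
        if layer == "B":
            return np.array([position * self.strand_sep, 0.0, 0.0])
        z = self.layer_sep if layer == "A" else -self.layer_sep
        return np.array([position * self.helix_sep, 0.0, z])


@dataclass
class CaModel:
    """An ordered C-alpha trace with per-residue SSE annotations.

    ``element_index`` holds, per residue, the chain index of the SSE it belongs
    to (-1 for loop residues); ``element_kind`` the matching ``H``/``E``/``-``
    code.  ``provenance`` records how a generated model was built.
    """

    coords: np.ndarray  # (N, 3) float64
    element_index: np.ndarray  # (N,) int, -1 for loops
    element_kind: np.ndarray  # (N,) '<U1', H / E / -
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.element_index = np.asarray(self.element_index, dtype=int)
        self.element_kind = np.asarray(self.element_kind, dtype="<U1")
        n = len(self.coords)
        if self.coords.shape != (n, 3) or len(self.element_index) != n or len(self.element_kind) != n:
            raise ValueError("inconsistent model arrays")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        idx = self.element_index[self.element_index >= 0]
        return len(np.unique(idx))

    def element_residues(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.element_index == k)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)


# ---------------------------------------------------------------------------
# filters

def _strand_chain_indices(elems: Sequence[Element]) -> list[int]:
    return [i for i, (l, _, _) in enumerate(elems) if l == "B"]


_LAYER_Z = {"A": 1.0, "B": 0.0, "C": -1.0}


def is_right_handed(ts: TopologyString, i: int) -> bool:
    """Chirality of the connection between consecutive strands *i* and *i*+1.

    Parallel beta crossovers in native proteins are almost always right
    handed.  On the ideal lattice the handedness is the sign of the triple
    product of the common strand direction, the lateral displacement between
    the two strands, and the mean out-of-sheet displacement of the SSEs the
    chain passes through between them.  Antiparallel pairs, and connections
    that never leave the sheet plane, carry no handedness constraint and
    return True.
    """
    elems = ts._tuples() if isinstance(ts, TopologyString) else tuple(ts)
    sidx = _strand_chain_indices(elems)
    if not 0 <= i < len(sidx) - 1:
        raise IndexError(f"no strand pair {i}")
    ia, ib = sidx[i], sidx[i + 1]
    (_, pa, da), (_, pb, db) = elems[ia], elems[ib]
    if da != db:
        return True  # antiparallel: constraint not applicable
    between = [elems[k] for k in range(ia + 1, ib)]
    zbar = float(np.mean([_LAYER_Z[l] for l, _, _ in between])) if between else 0.0
    if zbar == 0.0:
        return True  # connection stays in the sheet plane: no crossover face
    return da * (pb - pa) * zbar > 0


def _loop_faces_and_spans(
    elems: Sequence[Element], form: Form
) -> list[tuple[str, float, float]]:
    """Face label and lateral span of the loop after each element but the last.

    Faces: ``top``/``bottom`` for loops passing over/under the sheet,
    ``north``/``south`` for loops wrapping around a sheet end (antiparallel
    hairpins and helix-layer-to-helix-layer connections).
    """
    out = []
    for (l1, p1, d1), (l2, p2, d2) in zip(elems, elems[1:]):
        x1 = p1 * (form.strand_sep if l1 == "B" else form.helix_sep)
        x2 = p2 * (form.strand_sep if l2 == "B" else form.helix_sep)
        zsum = _LAYER_Z[l1] + _LAYER_Z[l2]
        if zsum > 0:
            face = "top"
        elif zsum < 0:
            face = "bottom"
        elif l1 == "B" and l2 == "B":
            if d1 == d2:  # parallel crossover: routed over its right-handed face
                face = "top" if d1 * (x2 - x1) > 0 else "bottom"
            else:  # hairpin at the exit end of the first strand
                face = "north" if d1 > 0 else "south"
        else:  # A-to-C: wraps around the exit end of the first helix
            face = "north" if d1 > 0 else "south"
        out.append((face, min(x1, x2), max(x1, x2)))
    return out


def has_loop_crossing(ts: TopologyString, form: Form | None = None) -> bool:
    """True iff two loops on the same face of the sheet cross.

    Loops are drawn between the lattice slots of the elements they join in
    the 2D projection onto that face; two same-face loops cross exactly when
    their lateral spans strictly interleave (nested or disjoint spans never
    cross, and loops on opposite faces cannot touch).
    """
    if form is None:
        form = Form(4, 8, 4)
    elems = ts._tuples() if isinstance(ts, TopologyString) else tuple(ts)
    loops = _loop_faces_and_spans(elems, form)
    for (fa, alo, ahi), (fb, blo, bhi) in itertools.combinations(loops, 2):
        if fa != fb:
            continue
        if (alo < blo < ahi < bhi) or (blo < alo < bhi < ahi):
            return True
    return False


def _passes_filters(elems: Sequence[Element], form: Form) -> bool:
    n_strands = sum(1 for l, _, _ in elems if l == "B")
    for i in range(n_strands - 1):
        if not is_right_handed_tuple(elems, i):
            return False
    return not has_loop_crossing(elems, form)


def is_right_handed_tuple(elems: Sequence[Element], i: int) -> bool:
    """Tuple-level fast path of :func:`is_right_handed` (used by enumeration)."""
    sidx = _strand_chain_indices(elems)
    ia, ib = sidx[i], sidx[i + 1]
    (_, pa, da), (_, pb, db) = elems[ia], elems[ib]
    if da != db:
        return True
    z = 0.0
    cnt = 0
    for l, _, _ in elems[ia + 1 : ib]:
        z += _LAYER_Z[l]
        cnt += 1
    if cnt == 0 or z == 0.0:
        return True
    return da * (pb - pa) * z > 0


# ---------------------------------------------------------------------------
# enumeration

def enumerate_folds(form: Form, n_helices: int, n_strands: int) -> list[TopologyString]:
    """All topologically distinct folds of the given SSE counts on *form*.

    Every assignment of the chain's SSEs to lattice slots and directions is
    generated (including the interleaving of helices and strands along the
    chain), folds with a left-handed parallel crossover or a loop crossing are
    removed, and the survivors are deduplicated under canonicalization.  The
    result is sorted lexicographically by serialized string.

    The labelling gauge is partly fixed up front (first strand points ``+``;
    on layer-symmetric forms the first helix is placed in layer A) purely as a
    pruning device: canonical deduplication makes the output independent of it.
    """
    if n_strands < 1:
        raise ValueError("at least one strand is required")
    if n_strands > form.n_b or n_helices > form.n_a + form.n_c:
        raise ValueError("SSEs exceed form capacity")

    m = n_helices + n_strands
    helix_slots = [("A", i) for i in range(form.n_a)] + [("C", i) for i in range(form.n_c)]
    gauge_first_helix = n_helices > 0 and form.n_a == form.n_c and form.n_a > 0

    found: set[tuple[Element, ...]] = set()
    for helix_chain_pos in itertools.combinations(range(m), n_helices):
        is_helix = [False] * m
        for k in helix_chain_pos:
            is_helix[k] = True
        for strand_perm in itertools.permutations(range(n_strands)):
            for strand_dirs in itertools.product((1, -1), repeat=n_strands - 1):
                sdirs = (1,) + strand_dirs  # first strand gauge-fixed to +
                for hslots in itertools.permutations(helix_slots, n_helices):
                    if gauge_first_helix and hslots and hslots[0][0] != "A":
                        continue
                    for hdirs in itertools.product((1, -1), repeat=n_helices):
                        elems: list[Element] = []
                        si = hi = 0
                        for k in range(m):
                            if is_helix[k]:
                                layer, slot = hslots[hi]
                                elems.append((layer, slot, hdirs[hi]))
                                hi += 1
                            else:
                                elems.append(("B", strand_perm[si], sdirs[si]))
                                si += 1
                        t = tuple(elems)
                        if _passes_filters(t, form):
                            found.add(_canonical_tuples(t))
    strings = sorted(
        (TopologyString._from_tuples(t) for t in found), key=format_topology
    )
    return strings


# ---------------------------------------------------------------------------
# model building

def _element_trace(layer: str, position: int, direction: int, length: int, form: Form) -> np.ndarray:
    """Ideal C-alpha trace of one SSE, centered on its lattice slot."""
    center = form.slot_center(layer, position)
    j = np.arange(length)
    if layer == "B":
        y = (j - (length - 1) / 2.0) * STRAND_RISE * direction
        x = np.where(j % 2 == 0, -_STRAND_WOBBLE, _STRAND_WOBBLE)
        pts = np.column_stack([center[0] + x, y, np.full(length, center[2])])
    else:
        y = (j - (length - 1) / 2.0) * HELIX_RISE * direction
        phase = j * HELIX_TWIST
        # right-handed alpha-helix about its axis for either chain direction
        x = HELIX_RADIUS * np.cos(phase)
        z = -direction * HELIX_RADIUS * np.sin(phase)
        pts = np.column_stack([center[0] + x, y, center[2] + z])
    return pts


def _place_final_loop_residue(
    p: np.ndarray, t: np.ndarray, placed: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """A point at CA_BOND from both *p* and *t*, clash-free, or None."""
    d = np.linalg.norm(t - p)
    if d > 2 * CA_BOND + 1e-6 or d < 1e-9:
        return None
    mid = 0.5 * (p + t)
    rad2 = CA_BOND**2 - (d / 2.0) ** 2
    rad = math.sqrt(max(rad2, 0.0))
    axis = (t - p) / d
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    for _ in range(40):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        cand = mid + rad * (math.cos(ang) * u + math.sin(ang) * v)
        if len(placed) < 2 or np.min(np.linalg.norm(placed[:-1] - cand, axis=1)) >= CLASH_DIST:
            return cand
    return None


def _build_loop(
    start: np.ndarray,
    target: np.ndarray,
    length: int,
    placed: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Self-avoiding biased random walk of *length* residues joining two points.

    The walk takes CA_BOND steps, keeps at least CLASH_DIST from previously
    placed atoms, and is steered so that the remaining bonds can always close
    the gap; the final residue is placed exactly on the circle at bond length
    from both its predecessor and the target.
    """
    gap = float(np.linalg.norm(target - start))
    if gap > (length + 1) * CA_BOND:
        raise BuildError("loop length infeasible")
    for _ in range(80):  # whole-loop restarts
        pts: list[np.ndarray] = []
        p = start.copy()
        ok = True
        for j in range(1, length + 1):
            remaining = length + 1 - j  # bonds left after this residue
            if remaining == 1:
                all_placed = np.vstack([placed] + [q[None, :] for q in pts] + [p[None, :]])
                cand = _place_final_loop_residue(p, target, all_placed, rng)
                if cand is None:
                    ok = False
                    break
                pts.append(cand)
                break
            placed_now = np.vstack([placed] + [q[None, :] for q in pts])
            to_t = target - p
            d_now = np.linalg.norm(to_t)
            # bias toward the target, harder when the remaining bonds have
            # little slack; the bias decays over proposals so the cone widens
            # until a clash-free route is found
            slack = (remaining + 1) * CA_BOND - d_now
            w_base = float(np.clip(1.0 - slack / (4.0 * CA_BOND), 0.6, 0.92))
            n_try = 150
            chosen = None
            for lo in (0, 24):  # cheap first batch, full fallback
                hi = 24 if lo == 0 else n_try
                u = rng.normal(size=(hi - lo, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                w = w_base * (1.0 - 0.6 * np.arange(lo, hi) / n_try)
                steps = w[:, None] * (to_t / max(d_now, 1e-9)) + (1.0 - w[:, None]) * u
                steps *= CA_BOND / np.linalg.norm(steps, axis=1, keepdims=True)
                cands = p + steps
                d_new = np.linalg.norm(target - cands, axis=1)
                feasible = d_new <= remaining * CA_BOND + 1e-7
                if feasible.any():
                    cands = cands[feasible]
                    dmin = np.min(
                        np.linalg.norm(cands[:, None, :] - placed_now[None, :, :], axis=2),
                        axis=1,
                    )
                    clear = dmin >= CLASH_DIST
                    if clear.any():
                        chosen = cands[int(np.argmax(clear))]
                        break
            if chosen is None:
                ok = False
                break
            pts.append(chosen)
            p = chosen
        if ok and len(pts) == length:
            return np.array(pts)
    raise BuildError("loop construction failed (persistent clashes)")


def minimum_loop_lengths(
    ts: TopologyString,
    sse_lengths: Sequence[int],
    form: Form | None = None,
    margin: float = 1.3,
) -> list[int]:
    """Loop residue counts able to span the inter-element gaps comfortably.

    A loop of L residues contributes L+1 virtual bonds of CA_BOND; the
    *margin* leaves slack so the self-avoiding walk can route around the
    elements it departs from instead of being forced fully taut.
    """
    if form is None:
        form = Form(4, 8, 4)
    elems = ts._tuples()
    traces = [
        _element_trace(l, p, d, L, form) for (l, p, d), L in zip(elems, sse_lengths)
    ]
    out = []
    for a, b in zip(traces, traces[1:]):
        gap = float(np.linalg.norm(b[0] - a[-1]))
        out.append(max(1, math.ceil(gap * margin / CA_BOND) - 1))
    return out


def build_ca_model(
    ts: TopologyString,
    sse_lengths: Sequence[int],
    loop_lengths: Sequence[int],
    seed: int,
    form: Form | None = None,
) -> CaModel:
    """Build an ideal-geometry C-alpha model realizing topology *ts*.

    One residue count per SSE (strands >= 3, helices >= 4, at most 25) and one
    per connecting loop (1..15).  Loops are seeded pseudo-random self-avoiding
    walks; identical inputs and seed give bitwise-identical coordinates.
    """
    if form is None:
        form = Form(4, 8, 4)
    elems = ts._tuples()
    if len(sse_lengths) != len(elems):
        raise ValueError("one length per SSE required")
    if len(loop_lengths) != len(elems) - 1:
        raise ValueError("one length per loop required")
    for (layer, _, _), L in zip(elems, sse_lengths):
        lo = 3 if layer == "B" else 4
        if not lo <= L <= 25:
            raise ValueError(f"SSE length {L} outside [{lo}, 25]")
    for L in loop_lengths:
        if not 1 <= L <= 15:
            raise ValueError(f"loop length {L} outside [1, 15]")

    rng = np.random.default_rng(seed)
    traces = [
        _element_trace(l, p, d, L, form) for (l, p, d), L in zip(elems, sse_lengths)
    ]

    coords: list[np.ndarray] = [traces[0]]
    index: list[np.ndarray] = [np.full(len(traces[0]), 0)]
    kind: list[np.ndarray] = [
        np.full(len(traces[0]), "E" if elems[0][0] == "B" else "H")
    ]
    for k in range(1, len(elems)):
        placed = np.vstack(coords)
        loop = _build_loop(placed[-1], traces[k][0], loop_lengths[k - 1], placed, rng)
        coords.append(loop)
        index.append(np.full(len(loop), -1))
        kind.append(np.full(len(loop), "-"))
        coords.append(traces[k])
        index.append(np.full(len(traces[k]), k))
        kind.append(np.full(len(traces[k]), "E" if elems[k][0] == "B" else "H"))

    model = CaModel(
        coords=np.vstack(coords),
        element_index=np.concatenate(index),
        element_kind=np.concatenate(kind),
        provenance={
            "topology": format_topology(ts),
            "seed": int(seed),
            "sse_lengths": [int(x) for x in sse_lengths],
            "loop_lengths": [int(x) for x in loop_lengths],
            "form": form.name,
        },
    )
    return model


# ---------------------------------------------------------------------------
# topology extraction from coordinates

def _element_axes(model: CaModel) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """Centroid, N-to-C axis and kind for each annotated element in chain order."""
    centroids, axes, kinds = [], [], []
    n_el = int(model.element_index.max()) + 1
    for k in range(n_el):
        res = model.element_residues(k)
        if len(res) < 2:
            raise TopologyError(f"element {k} has fewer than 2 residues")
        pts = model.coords[res]
        c = pts.mean(axis=0)
        centered = pts - c
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if axis @ (pts[-1] - pts[0]) < 0:
            axis = -axis
        centroids.append(c)
        axes.append(axis)
        kinds.append(str(model.element_kind[res[0]]))
    return centroids, axes, kinds


def extract_topology(
    model: CaModel,
    helix_sep: float = 10.0,
    ambiguity_tol: float = 3.0,
) -> TopologyString:
    """Recover the canonical topology string of an annotated C-alpha model.

    Fits a three-layer frame: the strand-axis direction of the first strand,
    a lateral axis from the scatter of strand centroids, and the layer normal
    completing a right-handed frame.  Each element gets a layer from its
    signed distance to the sheet plane (a helix closer than *ambiguity_tol*
    to the plane is rejected as ambiguous), strands get positions by
    adjacency rank along the lateral axis, helices by rounded lattice slot
    (gaps preserved), and directions by the sign of the axis projection.
    The result is canonical, hence invariant under rigid motion; mirroring
    the coordinates changes the string for chiral folds.
    """
    centroids, axes, kinds = _element_axes(model)
    strand_ids = [k for k, kd in enumerate(kinds) if kd == "E"]
    if not strand_ids:
        raise TopologyError("no sheet layer")

    # strand-axis direction, signed like the first strand
    ref = axes[strand_ids[0]]
    y = np.zeros(3)
    for k in strand_ids:
        a = axes[k]
        y += a if a @ ref >= 0 else -a
    y /= np.linalg.norm(y)

    origin = np.mean([centroids[k] for k in strand_ids], axis=0)
    if len(strand_ids) >= 2:
        m = np.array([centroids[k] - origin for k in strand_ids])
        m -= np.outer(m @ y, y)
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        x = vt[0]
    else:
        x = np.array([1.0, 0.0, 0.0])
        x -= (x @ y) * y
        if np.linalg.norm(x) < 1e-6:
            x = np.array([0.0, 0.0, 1.0]) - (np.array([0.0, 0.0, 1.0]) @ y) * y
        x /= np.linalg.norm(x)
    z = np.cross(x, y)  # right-handed frame (x, y, z)

    layers: list[str] = []
    for k, kd in enumerate(kinds):
        zc = float((centroids[k] - origin) @ z)
        if kd == "E":
            layers.append("B")
        else:
            if abs(zc) < ambiguity_tol:
                raise TopologyError("ambiguous layer assignment")
            layers.append("A" if zc > 0 else "C")

    xs = [float((centroids[k] - origin) @ x) for k in range(len(kinds))]
    positions = [0] * len(kinds)
    # strands: adjacency rank along the lateral axis
    order = sorted(strand_ids, key=lambda k: xs[k])
    for rank, k in enumerate(order):
        positions[k] = rank
    # helices: rounded lattice slots per layer, preserving gaps
    for layer in ("A", "C"):
        ids = [k for k in range(len(kinds)) if layers[k] == layer]
        if not ids:
            continue
        x0 = min(xs[k] for k in ids)
        for k in ids:
            positions[k] = int(round((xs[k] - x0) / helix_sep))

    elems = tuple(
        (layers[k], positions[k], 1 if axes[k] @ y >= 0 else -1)
        for k in range(len(kinds))
    )
    return TopologyString._from_tuples(_canonical_tuples(elems))


# ---------------------------------------------------------------------------
# PDB input/output (C-alpha only) and a heuristic SSE assigner

def write_ca_pdb(model: CaModel, path, chain_id: str = "A") -> None:
    """Write the trace as C-alpha-only ATOM records, with a provenance sidecar.

    A generated model is accompanied by ``<path>.topology.txt`` holding its
    topology string and a JSON provenance block with the seed and lengths.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "decoy"
    mdl = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for i, (xyz, kd) in enumerate(zip(model.coords, model.element_kind), start=1):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))
    if model.provenance:
        side = str(path) + ".topology.txt"
        with open(side, "w") as fh:
            fh.write(model.provenance.get("topology", "") + "\n")
            fh.write(json.dumps(model.provenance) + "\n")


def read_ca_pdb(path, annotations=None) -> CaModel:
    """Read a C-alpha trace from a PDB file.

    *annotations*, when given, is the path of a sidecar JSON file with
    ``element_index`` and ``element_kind`` lists (one entry per residue); a
    model read without annotations can be annotated with
    :func:`assign_sse_from_ca`.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    coords = []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                ca = res.find_atom("CA", "*")
                if ca is not None:
                    coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        break
    coords = np.array(coords, dtype=float)
    n = len(coords)
    if annotations is not None:
        with open(annotations) as fh:
            ann = json.load(fh)
        idx = np.asarray(ann["element_index"], dtype=int)
        kind = np.asarray(ann["element_kind"], dtype="<U1")
        if len(idx) != n or len(kind) != n:
            raise ValueError("annotation length does not match residue count")
    else:
        idx = np.full(n, -1)
        kind = np.full(n, "-")
    return CaModel(coords=coords, element_index=idx, element_kind=kind)


def assign_sse_from_ca(model: CaModel) -> CaModel:
    """Heuristic SSE annotation from C-alpha geometry alone.

    Classifies residues over 5-residue windows using the virtual-bond
    distances d(i, i+3): about 5 A in an alpha-helix, above 9 A in an
    extended strand.  Runs shorter than 4 (helix) or 3 (strand) residues are
    dropped.  This is a coarse fallback for native traces lacking curated
    element definitions; curated annotations should be preferred.
    """
    xyz = model.coords
    n = len(xyz)
    code = np.full(n, "-", dtype="<U1")
    if n >= 4:
        d13 = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)
        for i in range(n - 3):
            if d13[i] < 6.0:
                code[i : i + 4] = np.where(code[i : i + 4] == "-", "H", code[i : i + 4])
            elif d13[i] > 9.0:
                for j in range(i, i + 4):
                    if code[j] == "-":
                        code[j] = "E"
    # enforce minimum run lengths and number the elements
    idx = np.full(n, -1)
    out_kind = np.full(n, "-", dtype="<U1")
    k = 0
    i = 0
    while i < n:
        c = code[i]
        j = i
        while j < n and code[j] == c:
            j += 1
        run = j - i
        if c == "H" and run >= 4 or c == "E" and run >= 3:
            idx[i:j] = k
            out_kind[i:j] = c
            k += 1
        i = j
    return CaModel(
        coords=xyz.copy(),
        element_index=idx,
        element_kind=out_kind,
        provenance=dict(model.provenance, sse_assignment="heuristic-ca"),
    )
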