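"""Residue-level structure alignment of C-alpha models.

Provides optimal rigid superposition (Kabsch), TM-score evaluation, a generic
iterated superposition / dynamic-programming aligner, and parsers for the text
output of external comparison tools.  The internal aligner is a stand-in for
published methods, not a reproduction of any of them: it seeds alignments from
gapless offsets and SSE correspondences and then alternates superposition,
distance rescoring and global-local dynamic programming (terminal gaps free)
until the residue pairing stops changing.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .decoygen import CaModel

__all__ = [
    "AlignmentResult",
    "AlignError",
    "ParseError",
    "kabsch_superpose",
    "tm_d0",
    "tm_from_distances",
    "tm_score",
    "iterative_align",
    "parse_external",
    "write_alignment_tsv",
]


class AlignError(ValueError):
    pass


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """A residue correspondence between two models.

    ``pairs`` is strictly increasing in both indices (no crossing
    correspondences), ``n`` the matched length, ``r`` the RMSD of the matched
    pairs after optimal superposition, ``tm`` the TM-score of the alignment.
    ``native_score`` carries an external tool's own score (e.g. a Z-score).
    """

    pairs: tuple[tuple[int, int], ...]
    n: int
    r: float
    tm: float
    method: str = "internal"
    native_score: float | None = None
    unalignable: bool = False
    partial: bool = False

    def __post_init__(self) -> None:
        if self.n != len(self.pairs) and not self.partial:
            raise AlignError("n does not match the number of pairs")
        ii = [i for i, _ in self.pairs]
        jj = [j for _, j in self.pairs]
        if ii != sorted(set(ii)) or jj != sorted(set(jj)):
            raise AlignError("pairs must be strictly increasing in both indices")

    def transposed(self) -> "AlignmentResult":
        return AlignmentResult(
            pairs=tuple((j, i) for i, j in self.pairs),
            n=self.n,
            r=self.r,
            tm=self.tm,
            method=self.method,
            native_score=self.native_score,
            unalignable=self.unalignable,
            partial=self.partial,
        )


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(
    P: np.ndarray,
    Q: np.ndarray,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched points (SVD form).

    Returns ``(R, t, rmsd)`` with a proper rotation (det +1) and translation
    such that ``R @ p + t`` best matches ``q`` over the matched pairs.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if pairs is not None:
        idx = np.asarray(pairs, int)
        P = P[idx[:, 0]]
        Q = Q[idx[:, 1]]
    if len(P) < 3 or len(P) != len(Q):
        raise AlignError("at least 3 matched pairs are required")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:  # rank < 2: collinear or coincident points
        raise AlignError("degenerate geometry: matched points are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (Pc @ R.T) - Qc
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# TM-score

def tm_d0(L: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 A."""
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def tm_from_distances(d: np.ndarray, L_norm: int) -> float:
    """TM-score sum for given matched-pair distances at a fixed superposition."""
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (np.asarray(d, float) / d0) ** 2)) / L_norm)


def _pair_coords(A: np.ndarray, B: np.ndarray, pairs) -> tuple[np.ndarray, np.ndarray]:
    idx = np.asarray(pairs, int)
    return A[idx[:, 0]], B[idx[:, 1]]


def _tm_refine(
    PA: np.ndarray, PB: np.ndarray, seed_sel: np.ndarray, L_norm: int, max_rounds: int = 30
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Iteratively superpose on close pairs; return the best TM sum and frame."""
    d0 = tm_d0(L_norm)
    sel = seed_sel
    best = 0.0
    bR = bt = None
    prev = None
    for _ in range(max_rounds):
        if sel.sum() < 3:
            sel = np.ones(len(PA), bool)
        try:
            R, t, _ = kabsch_superpose(PA[sel], PB[sel])
        except AlignError:
            return best, bR, bt
        d = np.linalg.norm(PA @ R.T + t - PB, axis=1)
        tm = tm_from_distances(d, L_norm)
        if tm > best:
            best, bR, bt = tm, R, t
        cut = max(d0 + 1.0, 4.5)
        new_sel = d < cut
        key = new_sel.tobytes()
        if key == prev:
            break
        prev = key
        sel = new_sel
    return best, bR, bt


def tm_score(
    A: CaModel | np.ndarray,
    B: CaModel | np.ndarray,
    aln: AlignmentResult,
    normalize_by: int | str = "shorter",
) -> float:
    """TM-score of an alignment in its optimal-TM superposition frame.

    The superposition maximizing the TM sum is searched by seeding from the
    full pair set and from contiguous fragments of it, each refined by
    iterating superposition on pairs closer than the distance cut.
    Normalization length defaults to the shorter chain.
    """
    CA = A.coords if isinstance(A, CaModel) else np.asarray(A, float)
    CB = B.coords if isinstance(B, CaModel) else np.asarray(B, float)
    if isinstance(normalize_by, str):
        if normalize_by == "shorter":
            L_norm = min(len(CA), len(CB))
        elif normalize_by == "longer":
            L_norm = max(len(CA), len(CB))
        elif normalize_by == "first":
            L_norm = len(CA)
        elif normalize_by == "second":
            L_norm = len(CB)
        else:
            raise ValueError(f"unknown normalization {normalize_by!r}")
    else:
        L_norm = int(normalize_by)
    if not aln.pairs:
        return 0.0
    PA, PB = _pair_coords(CA, CB, aln.pairs)
    m = len(PA)
    best = 0.0
    bR = bt = None
    seeds: list[np.ndarray] = [np.ones(m, bool)]
    for frac in (2, 4):
        w = max(4, m // frac)
        if w >= m:
            continue
        for start in range(0, m - w + 1, max(1, w // 2)):
            s = np.zeros(m, bool)
            s[start : start + w] = True
            seeds.append(s)
    for s in seeds:
        tm, R, t = _tm_refine(PA, PB, s, L_norm)
        if tm > best:
            best, bR, bt = tm, R, t
    if bR is None:
        return best
    # polish the best frame against the TM objective itself; superposition on
    # close pairs is only a surrogate and stops slightly short of the optimum
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def neg_tm(x: np.ndarray) -> float:
        R = Rotation.from_rotvec(x[:3]).as_matrix() @ bR
        d = np.linalg.norm(PA @ R.T + (bt + x[3:]) - PB, axis=1)
        return -tm_from_distances(d, L_norm)

    res = minimize(
        neg_tm, np.zeros(6), method="Nelder-Mead",
        options={"maxiter": 3000, "fatol": 1e-13, "xatol": 1e-10},
    )
    return max(best, -float(res.fun))


# ---------------------------------------------------------------------------
# global-local dynamic programming

def _dp_global_local(S: np.ndarray, gap_open: float, gap_extend: float) -> list[tuple[int, int]]:
    """Maximize alignment score with affine gaps, terminal gaps free.

    Three-state (match / gap-in-B / gap-in-A) dynamic programming with
    explicit traceback pointers; the optimum is taken over the last row and
    column so trailing gaps are not penalized.  Returns matched (i, j) pairs
    in increasing order.
    """
    LA, LB = S.shape
    NEG = -1e18
    M = [[NEG] * (LB + 1) for _ in range(LA + 1)]
    X = [[NEG] * (LB + 1) for _ in range(LA + 1)]  # gap in B (consumes A)
    Y = [[NEG] * (LB + 1) for _ in range(LA + 1)]  # gap in A (consumes B)
    tM = [[0] * (LB + 1) for _ in range(LA + 1)]  # predecessor state of M's diag
    tX = [[0] * (LB + 1) for _ in range(LA + 1)]  # 0: opened from M, 1: extended
    tY = [[0] * (LB + 1) for _ in range(LA + 1)]
    M[0][0] = 0.0
    for i in range(1, LA + 1):
        X[i][0] = 0.0  # free leading gap
    for j in range(1, LB + 1):
        Y[0][j] = 0.0
    Srows = S.tolist()
    for i in range(1, LA + 1):
        Si = Srows[i - 1]
        Mi, Mp = M[i], M[i - 1]
        Xi, Xp = X[i], X[i - 1]
        Yi, Yp = Y[i], Y[i - 1]
        tMi, tXi, tYi = tM[i], tX[i], tY[i]
        for j in range(1, LB + 1):
            dm, dx, dy = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            if dm >= dx and dm >= dy:
                Mi[j] = dm + Si[j - 1]
                tMi[j] = 0
            elif dx >= dy:
                Mi[j] = dx + Si[j - 1]
                tMi[j] = 1
            else:
                Mi[j] = dy + Si[j - 1]
                tMi[j] = 2
            a = Mp[j] - gap_open
            b = Xp[j] - gap_extend
            if a >= b:
                Xi[j] = a
                tXi[j] = 0
            else:
                Xi[j] = b
                tXi[j] = 1
            a = Mi[j - 1] - gap_open
            b = Yi[j - 1] - gap_extend
            if a >= b:
                Yi[j] = a
                tYi[j] = 0
            else:
                Yi[j] = b
                tYi[j] = 1
    # free trailing gaps: best end point on the last row or column
    best = (NEG, LA, LB, 0)
    for j in range(1, LB + 1):
        for state, mat in enumerate((M, X, Y)):
            v = mat[LA][j]
            if v > best[0]:
                best = (v, LA, j, state)
    for i in range(1, LA + 1):
        for state, mat in enumerate((M, X, Y)):
            v = mat[i][LB]
            if v > best[0]:
                best = (v, i, LB, state)
    _, i, j, state = best
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            state = tM[i][j]
            i -= 1
            j -= 1
        elif state == 1:
            state = 0 if tX[i][j] == 0 else 1
            i -= 1
        else:
            state = 0 if tY[i][j] == 0 else 2
            j -= 1
    pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# iterative aligner

def _sse_seed(A: CaModel, B: CaModel) -> list[tuple[int, int]] | None:
    """Pair residues of SSEs matched in chain order (same-kind elements)."""
    try:
        ka = [str(A.element_kind[A.element_residues(k)[0]]) for k in range(A.n_elements)]
        kb = [str(B.element_kind[B.element_residues(k)[0]]) for k in range(B.n_elements)]
    except (IndexError, ValueError):
        return None
    if not ka or not kb:
        return None
    pairs: list[tuple[int, int]] = []
    ja = jb = 0
    while ja < len(ka) and jb < len(kb):
        if ka[ja] == kb[jb]:
            ra = A.element_residues(ja)
            rb = B.element_residues(jb)
            m = min(len(ra), len(rb))
            oa = (len(ra) - m) // 2
            ob = (len(rb) - m) // 2
            pairs.extend(zip(ra[oa : oa + m].tolist(), rb[ob : ob + m].tolist()))
            ja += 1
            jb += 1
        elif len(ka) - ja > len(kb) - jb:
            ja += 1
        else:
            jb += 1
    return pairs if len(pairs) >= 3 else None


def _model_key(M: CaModel) -> bytes:
    return hashlib.sha256(np.round(M.coords, 3).tobytes()).digest()


def iterative_align(
    A: CaModel,
    B: CaModel,
    gap_open: float = 0.6,
    gap_extend: float = 0.05,
    dist_cutoff: float = 10.0,
    max_iter: int = 20,
) -> AlignmentResult:
    """Iterated superposition / dynamic-programming alignment of two models.

    Seeds from gapless diagonal offsets and from an SSE-element
    correspondence, then repeats: superpose on the current pairs, score all
    residue pairs by ``1 / (1 + (d / d0)^2)``, realign by global-local DP
    (terminal gaps free), until the pair set repeats or *max_iter* rounds.
    The iterate with the highest TM-score (ties: larger n) wins.
    Deterministic, and symmetric in its arguments up to transposition of the
    pair list.  If no seed yields at least 20 matched pairs the result is
    flagged ``unalignable``.
    """
    if len(A) < 20 or len(B) < 20:
        raise AlignError("models must have at least 20 residues")
    if (len(B), _model_key(B)) < (len(A), _model_key(A)):
        return iterative_align(
            B, A, gap_open=gap_open, gap_extend=gap_extend,
            dist_cutoff=dist_cutoff, max_iter=max_iter,
        ).transposed()

    CA, CB = A.coords, B.coords
    LA, LB = len(CA), len(CB)
    L_norm = min(LA, LB)
    d0 = tm_d0(L_norm)

    seeds: list[list[tuple[int, int]]] = []
    step = max(5, (LA + LB) // 10)
    offsets = sorted({0, step, -step, 2 * step, -2 * step})
    for off in offsets:
        lo = max(0, off)
        hi = min(LA, LB + off)
        if hi - lo >= 20:
            seeds.append([(i, i - off) for i in range(lo, hi)])
    sse = _sse_seed(A, B)
    if sse is not None:
        seeds.append(sse)

    best: tuple[float, int, tuple[tuple[int, int], ...]] | None = None
    for seed in seeds:
        pairs = seed
        seen: set[tuple[tuple[int, int], ...]] = set()
        for _ in range(max_iter):
            idx = np.asarray(pairs, int)
            pa, pb = CA[idx[:, 0]], CB[idx[:, 1]]
            d_prev = None
            try:
                R, t, _ = kabsch_superpose(pa, pb)
            except AlignError:
                break
            d_cur = np.linalg.norm(pa @ R.T + t - pb, axis=1)
            close = d_cur < dist_cutoff
            if close.sum() >= 3:
                R, t, _ = kabsch_superpose(pa[close], pb[close])
            moved = CA @ R.T + t
            D = cdist(moved, CB)
            S = 1.0 / (1.0 + (D / d0) ** 2)
            new_pairs = _dp_global_local(S, gap_open, gap_extend)
            if len(new_pairs) < 3:
                break
            key = tuple(new_pairs)
            tm_quick, _, _ = _tm_refine(
                CA[[i for i, _ in new_pairs]],
                CB[[j for _, j in new_pairs]],
                np.ones(len(new_pairs), bool),
                L_norm,
                max_rounds=6,
            )
            cand = (tm_quick, len(new_pairs), key)
            if best is None or cand[:2] > best[:2]:
                best = cand
            if key in seen:
                break
            seen.add(key)
            pairs = new_pairs

    if best is None or best[1] < 20:
        return AlignmentResult(
            pairs=(), n=0, r=float("nan"), tm=0.0, method="internal", unalignable=True
        )
    _, n, pairs = best
    _, _, rmsd = kabsch_superpose(CA, CB, pairs)
    aln = AlignmentResult(pairs=pairs, n=n, r=rmsd, tm=0.0, method="internal")
    tm = tm_score(A, B, aln)
    return AlignmentResult(pairs=pairs, n=n, r=rmsd, tm=tm, method="internal")


# ---------------------------------------------------------------------------
# external tool output parsers

def _pairs_from_gapped(seq1: str, seq2: str, marks: str | None) -> tuple[tuple[int, int], ...]:
    i = j = 0
    pairs = []
    for col, (a, b) in enumerate(zip(seq1, seq2)):
        aligned = a != "-" and b != "-"
        if aligned and (marks is None or (col < len(marks) and marks[col] in ":.")):
            pairs.append((i, j))
        if a != "-":
            i += 1
        if b != "-":
            j += 1
    return tuple(pairs)


def _parse_tmalign(text: str) -> AlignmentResult:
    m = re.search(r"Aligned length=\s*(\d+),\s*RMSD=\s*([\d.]+)", text)
    if m is None:
        raise ParseError("TM-align output: no 'Aligned length=' line found")
    n = int(m.group(1))
    r = float(m.group(2))
    tm_m = re.search(r"TM-score=\s*([\d.]+)", text)
    if tm_m is None:
        raise ParseError("TM-align output: no TM-score line found")
    tm = float(tm_m.group(1))
    lines = text.splitlines()
    pairs: tuple[tuple[int, int], ...] = ()
    for k, line in enumerate(lines):
        if '":" denotes' in line or "denotes residue pairs" in line:
            block = [l for l in lines[k + 1 :] if l.strip()]
            if len(block) >= 3:
                pairs = _pairs_from_gapped(block[0], block[2], block[1])
            break
    partial = not pairs
    return AlignmentResult(
        pairs=pairs, n=n, r=r, tm=tm, method="tmalign",
        native_score=tm, partial=partial,
    )


def _parse_dali(text: str) -> AlignmentResult:
    for ln, line in enumerate(text.splitlines(), start=1):
        m = re.match(
            r"\s*\d+:\s+\S+\s+([-\d.]+)\s+([-\d.]+)\s+(\d+)\s+(\d+)", line
        )
        if m:
            z = float(m.group(1))
            r = float(m.group(2))
            n = int(m.group(3))
            return AlignmentResult(
                pairs=(), n=n, r=r, tm=0.0, method="dali",
                native_score=z, partial=True,
            )
    raise ParseError("DALI output: no summary line found")


def _parse_sap(text: str) -> AlignmentResult:
    m = re.search(r"RMSd?\s*=\s*([\d.]+)\s*(?:\(|over)\s*(\d+)", text, re.IGNORECASE)
    if m is None:
        raise ParseError("SAP output: no RMSd summary line found")
    r = float(m.group(1))
    n = int(m.group(2))
    sm = re.search(r"(?:Final|Weighted)\s+score\s*=\s*([\d.]+)", text, re.IGNORECASE)
    score = float(sm.group(1)) if sm else None
    return AlignmentResult(
        pairs=(), n=n, r=r, tm=0.0, method="sap",
        native_score=score, partial=True,
    )


_DIALECTS = {"tmalign": _parse_tmalign, "dali": _parse_dali, "sap": _parse_sap}


def parse_external(path, dialect: str) -> AlignmentResult:
    """Parse the text output of TM-align, DALI or SAP into an AlignmentResult.

    Results without an explicit residue-pair section carry ``n`` and ``r``
    only and are flagged ``partial``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    with open(path) as fh:
        text = fh.read()
    return _DIALECTS[dialect](text)


def write_alignment_tsv(path, rows: Sequence[tuple[str, str, AlignmentResult]]) -> None:
    """Write alignment results as TSV: idA, idB, n, r, tm, method."""
    with open(path, "w") as fh:
        fh.write("idA\tidB\tn\tr\ttm\tmethod\n")
        for ida, idb, aln in rows:
            fh.write(f"{ida}\t{idb}\t{aln.n}\t{aln.r:.4f}\t{aln.tm:.4f}\t{aln.method}\n")
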