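"""RNA secondary-structure folding restricted to single-hairpin topologies.

Animal pre-miRNAs fold into one stem-loop: a helix interrupted by bulges and
internal loops, closed by a single terminal loop, with no multibranch loops.
This module computes the minimum free energy (MFE) structure over exactly that
structure class with a Turner-style nearest-neighbour energy model: stacking
energies over the six canonical pair types (Watson-Crick + GU wobble),
size-dependent hairpin-loop, bulge and internal-loop initiation penalties,
an asymmetry penalty for lopsided internal loops, and a terminal penalty for
AU/GU-closed helices.

Restricting the topology keeps the dynamic program quadratic in sequence
length (with a capped loop size) and makes exhaustive enumeration feasible on
short sequences, which is how the DP is validated.  Energies are kcal/mol at
37 degrees C; parameter values are this package's own nearest-neighbour set,
chosen to rank structures the way standard folding engines do.  MFE values
are therefore comparable across candidates scored here, not against other
programs' outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["FoldResult", "fold_hairpin", "MAX_LOOP_GAP"]

# per-strand cap on bulge/internal-loop size considered by the model
MAX_LOOP_GAP = 10

_INF = 1e9

# base coding: A=0, C=1, G=2, U/T=3
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair coding: 0 = not pairable; 1=CG 2=GC 3=AU 4=UA 5=GU 6=UG
PAIR_CODE = np.zeros((4, 4), dtype=np.int64)
PAIR_CODE[1, 2] = 1  # C-G
PAIR_CODE[2, 1] = 2  # G-C
PAIR_CODE[0, 3] = 3  # A-U
PAIR_CODE[3, 0] = 4  # U-A
PAIR_CODE[2, 3] = 5  # G-U
PAIR_CODE[3, 2] = 6  # U-G

# stacking energy of outer pair p on inner pair q, kcal/mol
# rows/cols: index 0 unused, then CG GC AU UA GU UG
STACK = np.full((7, 7), _INF)
STACK[1:, 1:] = np.array(
    [
        #  CG    GC    AU    UA    GU    UG
        [-3.3, -2.4, -2.1, -2.1, -1.4, -2.1],  # CG
        [-3.4, -3.3, -2.2, -2.4, -2.5, -1.5],  # GC
        [-2.1, -2.2, -0.9, -1.1, -0.6, -1.4],  # AU
        [-2.4, -2.1, -1.3, -0.9, -1.0, -1.3],  # UA
        [-2.1, -2.5, -0.5, -1.4, -0.5, 0.3],   # GU
        [-1.4, -1.5, -0.6, -1.0, 0.3, -0.5],   # UG
    ]
)

# loop initiation penalties by size; Jacobson-Stockmayer log extrapolation
_RT_COEF = 1.08  # 1.75 * R * T at 310 K, kcal/mol


def _extrapolated(table: dict[int, float], n: int, ref: int) -> float:
    if n in table:
        return table[n]
    return table[ref] + _RT_COEF * math.log(n / ref)


_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.7, 9: 4.8, 10: 4.9}
_INTERNAL_INIT = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.0, 7: 2.1, 8: 2.3, 9: 2.4, 10: 2.5}

MAX_SEQ_LEN = 250

HAIRPIN_E = np.full(MAX_SEQ_LEN + 1, _INF)
for _n in range(3, MAX_SEQ_LEN + 1):
    HAIRPIN_E[_n] = _extrapolated(_HAIRPIN_INIT, _n, 9)

BULGE_E = np.full(MAX_LOOP_GAP + 1, _INF)
for _n in range(1, MAX_LOOP_GAP + 1):
    BULGE_E[_n] = _BULGE_INIT[_n]

INTERNAL_E = np.full(2 * MAX_LOOP_GAP + 1, _INF)
for _n in range(2, 2 * MAX_LOOP_GAP + 1):
    INTERNAL_E[_n] = _extrapolated(_INTERNAL_INIT, _n, 10)

ASYMMETRY_COEF = 0.5
ASYMMETRY_MAX = 3.0
TERMINAL_AU = 0.5  # closing-pair penalty for AU/UA/GU/UG helix ends


@njit(cache=True)
def _loop_energy(pij, pkl, m_gap, s_gap, stack, bulge_e, internal_e):
    """Energy of the loop joining outer pair (type pij) to inner pair (type pkl)."""
    if m_gap == 0 and s_gap == 0:
        return stack[pij, pkl]
    if m_gap + s_gap == 1:
        # single-nucleotide bulge: helix stacking is preserved across it
        return bulge_e[1] + stack[pij, pkl]
    if m_gap == 0 or s_gap == 0:
        return bulge_e[m_gap + s_gap]
    asym = ASYMMETRY_COEF * abs(m_gap - s_gap)
    if asym > ASYMMETRY_MAX:
        asym = ASYMMETRY_MAX
    return internal_e[m_gap + s_gap] + asym


@njit(cache=True)
def _fold_dp(codes, pair_code, stack, hairpin_e, bulge_e, internal_e, max_gap):
    """Fill E[i,j] = min energy of a hairpin structure closed by pair (i,j).

    Returns (E, CK, CL): CK/CL give the inner pair chosen at (i,j), or -1 when
    the optimum closes the terminal loop directly.
    """
    n = codes.shape[0]
    E = np.full((n, n), _INF)
    CK = np.full((n, n), -1, dtype=np.int64)
    CL = np.full((n, n), -1, dtype=np.int64)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            pij = pair_code[codes[i], codes[j]]
            if pij == 0:
                continue
            best = hairpin_e[j - i - 1]
            bk = -1
            bl = -1
            kmax = i + 1 + max_gap
            if kmax > j - 4:
                kmax = j - 4
            for k in range(i + 1, kmax + 1):
                lmin = j - 1 - max_gap
                if lmin < k + 4:
                    lmin = k + 4
                for l in range(lmin, j):
                    if E[k, l] >= _INF:
                        continue
                    pkl = pair_code[codes[k], codes[l]]
                    e = _loop_energy(pij, pkl, k - i - 1, j - l - 1,
                                     stack, bulge_e, internal_e) + E[k, l]
                    if e < best:
                        best = e
                        bk = k
                        bl = l
            E[i, j] = best
            CK[i, j] = bk
            CL[i, j] = bl
    return E, CK, CL


@dataclass
class FoldResult:
    """MFE structure of a sequence under the single-hairpin model.

    structure: dot-bracket string; mfe: kcal/mol (<= 0, 0 means unfolded);
    pairs: nested (i, j) base pairs, outermost first, 0-based.
    """

    structure: str
    mfe: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def fold_hairpin(seq: str) -> FoldResult:
    """Fold ``seq`` into its minimum-free-energy single-hairpin structure.

    Returns the unfolded state (empty structure, mfe 0.0) when no hairpin has
    negative free energy.  Raises ValueError on non-ACGTU characters or on
    sequences outside 8..250 nt.
    """
    n = len(seq)
    if not 8 <= n <= MAX_SEQ_LEN:
        raise ValueError(f"sequence length {n} outside supported range 8..{MAX_SEQ_LEN}")
    codes = encode(seq)
    E, CK, CL = _fold_dp(codes, PAIR_CODE, STACK, HAIRPIN_E, BULGE_E, INTERNAL_E,
                         MAX_LOOP_GAP)
    best = 0.0
    bi = bj = -1
    for i in range(n):
        for j in range(i + 4, n):
            if E[i, j] >= _INF:
                continue
            pij = PAIR_CODE[codes[i], codes[j]]
            total = E[i, j] + (TERMINAL_AU if pij >= 3 else 0.0)
            if total < best:
                best = total
                bi, bj = i, j
    if bi < 0:
        return FoldResult(structure="." * n, mfe=0.0, pairs=[])
    pairs = []
    i, j = bi, bj
    while i >= 0:
        pairs.append((int(i), int(j)))
        i, j = CK[i, j], CL[i, j]
    struct = ["."] * n
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    return FoldResult(structure="".join(struct), mfe=round(float(best), 6), pairs=pairs)
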