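"""Independent reference computations used to validate the implementation.

These re-derive results by direct search or exact arithmetic, sharing only
the model *parameters* (energy tables, test definition) with the package —
never its algorithms.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

from mirswim import fold as F

INF = math.inf


def _loop_energy(p, q, mg, sg):
    if mg == 0 and sg == 0:
        return float(F.STACK[p, q])
    if mg + sg == 1:
        return float(F.BULGE_E[1] + F.STACK[p, q])
    if mg == 0 or sg == 0:
        return float(F.BULGE_E[mg + sg])
    asym = min(F.ASYMMETRY_COEF * abs(mg - sg), F.ASYMMETRY_MAX)
    return float(F.INTERNAL_E[mg + sg]) + asym


def mfe_by_search(seq: str) -> float:
    """MFE over all nested single-hairpin structures, by memoized top-down
    search over inner-pair choices (independent of the bottom-up DP)."""
    codes = [F._BASE_CODE[c] for c in seq.upper()]
    n = len(codes)

    def pair(i, j):
        return int(F.PAIR_CODE[codes[i], codes[j]])

    @lru_cache(maxsize=None)
    def closed(i, j):
        p = pair(i, j)
        if p == 0:
            return INF
        best = float(F.HAIRPIN_E[j - i - 1]) if j - i - 1 >= 3 else INF
        for k in range(i + 1, j):
            mg = k - i - 1
            if mg > F.MAX_LOOP_GAP:
                break
            for l in range(max(k + 4, j - 1 - F.MAX_LOOP_GAP), j):
                q = pair(k, l)
                if q == 0:
                    continue
                inner = closed(k, l)
                if inner == INF:
                    continue
                e = _loop_energy(p, q, mg, j - l - 1) + inner
                if e < best:
                    best = e
        return best

    best_total = 0.0
    for i in range(n):
        for j in range(i + 4, n):
            p = pair(i, j)
            if p == 0:
                continue
            e = closed(i, j)
            if e == INF:
                continue
            e += F.TERMINAL_AU if p >= 3 else 0.0
            best_total = min(best_total, e)
    return best_total


def enumerate_all_structures(seq: str) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """Every legal single-hairpin structure with its energy (tiny n only).

    A structure is a chain of nested pairs closed by a terminal loop of at
    least 3 nt, with per-strand loop gaps capped as in the model.
    """
    codes = [F._BASE_CODE[c] for c in seq.upper()]
    n = len(codes)

    def pair(i, j):
        return int(F.PAIR_CODE[codes[i], codes[j]])

    out = []

    def extend(chain, i, j, energy):
        # option 1: close with a terminal loop
        if j - i - 1 >= 3:
            out.append((tuple(chain), energy + float(F.HAIRPIN_E[j - i - 1])))
        # option 2: add a nested inner pair
        p = pair(i, j)
        for k in range(i + 1, j):
            mg = k - i - 1
            if mg > F.MAX_LOOP_GAP:
                break
            for l in range(max(k + 4, j - 1 - F.MAX_LOOP_GAP), j):
                q = pair(k, l)
                if q == 0:
                    continue
                extend(chain + [(k, l)], k, l,
                       energy + _loop_energy(p, q, mg, j - l - 1))

    for i in range(n):
        for j in range(i + 4, n):
            p = pair(i, j)
            if p == 0:
                continue
            term = F.TERMINAL_AU if p >= 3 else 0.0
            extend([(i, j)], i, j, term)
    return out


def audic_claverie_p(x: int, y: int, n1: int, n2: int) -> float:
    """Symmetrized two-sided exact-count p-value by direct tail summation.

    P(y|x) proportional to (N2/N1)^y (x+y)!/(x! y! (1+N2/N1)^(x+y)),
    normalized; smaller inclusive tail doubled and capped, averaged over
    both conditioning directions.  Exact rational arithmetic throughout.
    """

    def directional(x, y, n1, n2):
        pa = Fraction(n2, n1 + n2)
        pb = Fraction(n1, n1 + n2)

        def pmf(yy):
            return math.comb(x + yy, yy) * pa ** yy * pb ** (x + 1)

        lo = sum(pmf(t) for t in range(0, y + 1))
        hi = 1 - sum(pmf(t) for t in range(0, y))
        return min(Fraction(1), 2 * min(lo, hi))

    p = (directional(x, y, n1, n2) + directional(y, x, n2, n1)) / 2
    return float(min(Fraction(1), p))


def naive_genome_hits(genome: dict[str, str], query: str):
    """All perfect hits of query on both strands by exhaustive string scan."""
    from mirswim.annotate import revcomp
    hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for chrom, seq in genome.items():
            start = seq.find(q)
            while start != -1:
                hits.append((chrom, start, start + len(query), strand))
                start = seq.find(q, start + 1)
    return sorted(hits)


def naive_seed_sites(mirna: str, transcript: str):
    """Seed-site count by brute-force window comparison."""
    from mirswim.annotate import revcomp
    mir = mirna.upper().replace("U", "T")
    tx = transcript.upper().replace("U", "T")
    sites = []
    core = revcomp(mir[1:7])
    for t in range(len(tx) - 5):
        if tx[t:t + 6] != core:
            continue
        has_m8 = t > 0 and tx[t - 1] == revcomp(mir[7])
        has_a1 = t + 6 < len(tx) and tx[t + 6] == "A"
        if has_m8 and has_a1:
            sites.append((t - 1, t + 7, "8mer"))
        elif has_m8:
            sites.append((t - 1, t + 6, "7mer-m8"))
        elif has_a1:
            sites.append((t, t + 7, "7mer-A1"))
    return sites
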