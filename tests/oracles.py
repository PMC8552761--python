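"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the slowest, most transparent
route available (full dynamic programming with exhaustive traceback, per-base
interval scans, per-element membership counting, literal variant application)
so that the package's optimized paths are checked against code that shares
nothing with them.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def gotoh_all_optimal(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Global affine-gap alignment by explicit dynamic programming.

    Returns the optimal score and the set of identities attainable by *any*
    optimal alignment (exhaustive traceback; intended for short sequences).
    The first residue of a gap costs ``gap_open``, every further one
    ``gap_extend``; identity counts matching columns over columns where both
    sequences place a residue.
    """
    n, m = len(a), len(b)

    def s(x, y):
        return float(_BLOSUM62[x, y])

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # a-residue over a gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a over a b-residue
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + s(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    best = max(M[n][m], X[n][m], Y[n][m])

    def trace(i, j, state):
        """All (matches, aligned_cols) pairs over optimal paths into (i,j,state)."""
        if i == 0 and j == 0:
            return {(0, 0)}
        out = set()
        if state == "M":
            sc = s(a[i - 1], b[j - 1])
            add = 1 if a[i - 1] == b[j - 1] else 0
            for prev, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i - 1][j - 1] > NEG and mat[i - 1][j - 1] + sc == M[i][j]:
                    for mm, cc in trace(i - 1, j - 1, prev):
                        out.add((mm + add, cc + 1))
        elif state == "X":
            if j == 0:  # leading run of gaps in b
                return {(0, 0)}
            for prev, mat, cost in (("M", M, gap_open), ("X", X, gap_extend),
                                    ("Y", Y, gap_open)):
                if mat[i - 1][j] > NEG and mat[i - 1][j] - cost == X[i][j]:
                    out |= trace(i - 1, j, prev)
        else:
            if i == 0:  # leading run of gaps in a
                return {(0, 0)}
            for prev, mat, cost in (("M", M, gap_open), ("Y", Y, gap_extend),
                                    ("X", X, gap_open)):
                if mat[i][j - 1] > NEG and mat[i][j - 1] - cost == Y[i][j]:
                    out |= trace(i, j - 1, prev)
        return out

    results: set[tuple[int, int]] = set()
    for state, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[n][m] == best:
            results |= trace(n, m, state)
    identities = {mm / cc if cc else 0.0 for mm, cc in results}
    return best, identities


def brute_location(footprint: tuple[int, int], genes) -> str:
    """Per-base scan of a variant footprint against gene structure."""
    labels = set()
    for pos in range(footprint[0], footprint[1] + 1):
        label = "intergenic"
        for g in genes:
            if g.span[0] <= pos <= g.span[1]:
                label = "intron"
                for (s, e) in g.exons:
                    if s <= pos <= e:
                        label = "exon"
                        break
            if label == "exon":
                break
        labels.add(label)
    for priority in ("exon", "intron", "intergenic"):
        if priority in labels:
            return priority
    raise AssertionError("unreachable")


def k_of_n_membership(sets, k):
    """Literal per-element membership count."""
    universe = set().union(*sets) if sets else set()
    return {x for x in universe if sum(x in s for s in sets) >= k}


def apply_variants(sequence: str, records) -> str:
    """Literal left-to-right application of anchored variant records."""
    out = []
    cursor = 0
    for rec in sorted(records, key=lambda r: r.pos):
        start = rec.pos - 1
        assert start >= cursor, "overlapping records"
        assert sequence[start:start + len(rec.ref)].upper() == rec.ref.upper(), (
            f"REF mismatch at {rec.contig}:{rec.pos}"
        )
        out.append(sequence[cursor:start])
        out.append(rec.alt)
        cursor = start + len(rec.ref)
    out.append(sequence[cursor:])
    return "".join(out)
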