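"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration, linear
scans, double loops — and shares no code with the implementation under
test.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, product


# ---------------------------------------------------------------------------
# alignment oracles


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of ``a`` and ``b`` as aligned strings.

    Exponential; only for very short inputs.
    """
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(aligned_a: str, aligned_b: str, sub, gap_open: float,
                    gap_extend: float) -> float:
    """Affine-gap score of one explicit alignment.

    ``sub(x, y)`` gives the substitution score.  The first residue of each
    gap run costs ``gap_open``, every further residue ``gap_extend``.
    """
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            raise ValueError("gap-gap column")
        if ca == "-":
            total += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            total += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += sub(ca, cb)
            in_gap_a = in_gap_b = False
    return total


def brute_force_best_score(a: str, b: str, sub, gap_open: float,
                           gap_extend: float) -> float:
    """Maximum over every explicitly enumerated global alignment."""
    return max(
        score_alignment(ra, rb, sub, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def recursive_affine_score(a: str, b: str, sub, gap_open: float,
                           gap_extend: float) -> float:
    """Top-down recursion over (prefix of a, prefix of b, last move).

    An independent formulation of affine-gap global alignment: the state
    remembers only whether the previous column was a gap in ``a``, a gap
    in ``b``, or a substitution, so gap runs are priced correctly.
    """
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == 0 and j == 0:
            return 0.0
        options = []
        if i > 0 and j > 0:
            options.append(best(i - 1, j - 1, "M") + sub(a[i - 1], b[j - 1]))
        if i > 0:
            cost = gap_extend if last == "X" else gap_open
            options.append(best(i - 1, j, "X") + cost)
        if j > 0:
            cost = gap_extend if last == "Y" else gap_open
            options.append(best(i, j - 1, "Y") + cost)
        return max(options) if options else NEG

    # nothing follows the final column, so a trailing gap run is priced
    # from its right end: start the recursion in the substitution state
    return best(len(a), len(b), "M")


def linear_nw_score(a: str, b: str, sub, gap: float) -> float:
    """Classical single-matrix Needleman-Wunsch with linear gap cost."""
    n, m = len(a), len(b)
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gap
    for j in range(1, m + 1):
        F[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i][j] = max(
                F[i - 1][j - 1] + sub(a[i - 1], b[j - 1]),
                F[i - 1][j] + gap,
                F[i][j - 1] + gap,
            )
    return F[n][m]


# ---------------------------------------------------------------------------
# orthology / OPS / IPN oracles


def mutual_argmax_pairs(matrix: dict, cutoff: float) -> set:
    """RBH by brute force: per-query linear-scan argmax with lexicographic
    tie-break, both directions, mutual pairs at or above cutoff."""
    a_keys = sorted({p for p, _ in matrix})
    b_keys = sorted({q for _, q in matrix})

    def argmax(query, keys, get):
        best, best_v = None, None
        for s in keys:
            v = get(query, s)
            if best_v is None or v > best_v:
                best, best_v = s, v
        return best, best_v

    pairs = set()
    for p in a_keys:
        q, v = argmax(p, b_keys, lambda p, q: matrix[(p, q)])
        p2, _ = argmax(q, a_keys, lambda q, p: matrix[(p, q)])
        if p2 == p and v >= cutoff:
            pairs.add((p, q))
    return pairs


def brute_force_cliques(partner_maps: dict, species: list) -> set:
    """All one-per-species k-cliques by trying every accession combination.

    ``partner_maps[(s, t)]`` is the set of RBH pairs (acc_s, acc_t) with
    s < t in ``species`` order.
    """
    per_species = []
    for s in species:
        accs = set()
        for (x, y), pairs in partner_maps.items():
            if x == s:
                accs |= {p for p, _ in pairs}
            if y == s:
                accs |= {q for _, q in pairs}
        per_species.append(sorted(accs))
    cliques = set()
    for combo in product(*per_species):
        ok = True
        for (i, s), (j, t) in combinations(enumerate(species), 2):
            key = (s, t) if (s, t) in partner_maps else (t, s)
            pairs = partner_maps.get(key, set())
            pair = (combo[i], combo[j]) if key == (s, t) else (combo[j], combo[i])
            if pair not in pairs:
                ok = False
                break
        if ok:
            cliques.add(combo)
    return cliques


def brute_force_ipn_edges(ops_members: dict, networks: dict, cutoff: int) -> set:
    """IPN edges by a double loop over OPS pairs and species.

    ``ops_members``: ops_id -> {species: accession};
    ``networks``: species -> set of normalized accession pairs.
    """
    edges = set()
    for oi, oj in combinations(sorted(ops_members), 2):
        n = 0
        for s, net in networks.items():
            p, q = ops_members[oi][s], ops_members[oj][s]
            if (min(p, q), max(p, q)) in net:
                n += 1
        if n >= cutoff:
            edges.add((oi, oj))
    return edges
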