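"""Independent brute-force oracles used to check the fast implementations.

These are deliberately naive O(n*m) dynamic programs written without any
alignment library, so they share no code path with the package.  They are
only run on small instances.
"""

from __future__ import annotations

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def infix_edit_distance(query: str, target: str) -> int:
    """Minimum edit distance of ``query`` against any infix of ``target``."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)  # free start anywhere in target
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qc = query[i - 1]
        for j in range(1, n + 1):
            cost = 0 if qc == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free end anywhere in target


def infix_identity(a: str, b: str, both_strands: bool = True) -> float:
    """(Ls - best infix edit distance) / Ls, maximized over strands.

    Equals the matched-base identity of the end-gap-free alignment whenever
    the best alignment needs no internal target-consuming gaps (always true
    for the substitution-only and exact-fragment fixtures it is used on).
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    ls = len(query)
    best = infix_edit_distance(query, target)
    if both_strands:
        best = min(best, infix_edit_distance(revcomp(query), target))
    return (ls - best) / ls


def smith_waterman_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Affine-gap local alignment score; a length-k gap costs open + k*extend."""
    m, n = len(a), len(b)
    neg = float("-inf")
    h_prev = [0.0] * (n + 1)
    e_prev = [neg] * (n + 1)  # gap in a (consumes b)... tracked per row below
    best = 0.0
    # E: gap in sequence b direction (consumes a), F: consumes b
    e_col = [neg] * (n + 1)
    for i in range(1, m + 1):
        h_cur = [0.0] * (n + 1)
        f = neg
        ac = a[i - 1]
        for j in range(1, n + 1):
            e_col[j] = max(h_prev[j] - gap_open - gap_extend, e_col[j] - gap_extend)
            f = max(h_cur[j - 1] - gap_open - gap_extend, f - gap_extend)
            s = match if ac == b[j - 1] else mismatch
            h = max(0.0, h_prev[j - 1] + s, e_col[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
    return best


def greedy_cluster_bruteforce(contigs, identity_fn, threshold: float):
    """Reference greedy clustering: longest-first, join first representative
    with identity >= threshold, no prescreen.  Returns list of member-id lists.
    """
    order = sorted(range(len(contigs)), key=lambda i: (-len(contigs[i].residues), i))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for idx in order:
        rec = contigs[idx]
        for k, rep_seq in enumerate(reps):
            ident, _ = identity_fn(rec.residues, rep_seq)
            if ident + 1e-9 >= threshold:
                clusters[k].append(rec.id)
                break
        else:
            reps.append(rec.residues)
            clusters.append([rec.id])
    return clusters
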