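"""Independent test oracles, deliberately simple and separate from the
package's production code paths."""

from __future__ import annotations


def simple_affine_sw_score(q, s, score_fn, gap_open, gap_extend):
    """Plain three-matrix local-alignment DP in pure Python.

    A gap of length g costs gap_open + g * gap_extend.  Returns only the
    optimal score (0 when nothing aligns positively).
    """
    m, n = len(q), len(s)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend
            )
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score_fn(q[i - 1], s[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def exhaustive_local_score(q, s, score_fn, gap_open, gap_extend):
    """Enumerate every local alignment path explicitly (tiny inputs only)."""
    best = 0

    def rec(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i < len(q) and j < len(s):
            rec(i + 1, j + 1, score + score_fn(q[i], s[j]), "M")
        if i < len(q):
            cost = gap_extend if last == "D" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "D")
        if j < len(s):
            cost = gap_extend if last == "I" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "I")

    for i0 in range(len(q)):
        for j0 in range(len(s)):
            rec(i0, j0, 0, None)
    return best


def brute_force_containing(genes, chrom, start, end):
    """All genes strictly containing [start, end] on chrom, by linear scan."""
    return [
        g
        for g in genes
        if g.chrom == chrom and g.gene_start < start and end < g.gene_end
    ]
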