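"""Independent brute-force Smith-Waterman oracle for the test suite.

A plain O(n*m) Gotoh dynamic program with affine gaps, written directly from
the recurrences and sharing no code with the package's alignment backend.
Scoring convention matches the backend's contract: BLOSUM62 substitution
scores, a gap of length k costs gap_open + k * gap_extend (11 + k by
default).
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def local_align_score(query: str, subject: str,
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local alignment score (score only, no traceback)."""
    first_gap = gap_open + gap_extend  # cost of a length-1 gap
    n, m = len(query), len(subject)
    best = 0.0
    h_prev = [0.0] * (m + 1)
    e_prev = [NEG_INF] * (m + 1)
    for i in range(1, n + 1):
        h_row = [0.0] * (m + 1)
        e_row = [NEG_INF] * (m + 1)
        f = NEG_INF  # gap in subject, extended along j
        for j in range(1, m + 1):
            e_row[j] = max(h_prev[j] - first_gap, e_prev[j] - gap_extend)
            f = max(h_row[j - 1] - first_gap, f - gap_extend)
            sub = _BLOSUM62[query[i - 1], subject[j - 1]]
            h = max(0.0, h_prev[j - 1] + sub, e_row[j], f)
            h_row[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_row, e_row
    return best
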