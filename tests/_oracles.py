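"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (quadratic DP, exhaustive scans, full
gamete-table enumeration) kept free of any package internals so they can
arbitrate the production code.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def sw_score_one_strand(
    a: str, b: str, match: int = 2, mismatch: int = -3, gap_open: int = 5, gap_ext: int = 2
) -> int:
    """Smith-Waterman optimal local score, affine gaps costing
    gap_open + gap_ext * k for a gap of length k.  O(len(a)*len(b))."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    h_prev = [0] * (m + 1)
    e_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        h_cur = [0] * (m + 1)
        e_cur = [NEG] * (m + 1)
        f = NEG
        for j in range(1, m + 1):
            e = max(e_prev[j] - gap_ext, h_prev[j] - gap_open - gap_ext)
            f = max(f - gap_ext, h_cur[j - 1] - gap_open - gap_ext)
            diag = h_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(0, diag, e, f)
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def sw_score(a: str, b: str, **kw) -> int:
    """Best local score over both strands of the query."""
    return max(sw_score_one_strand(a, b, **kw), sw_score_one_strand(revcomp(a), b, **kw))


def suffix_scan(primer: str, subjects: list[str]) -> int:
    """Longest primer 3'-suffix occurring exactly anywhere in any subject
    (either strand), by comparing every suffix at every position."""
    texts = [t for s in subjects for t in (s, revcomp(s))]
    best = 0
    for k in range(1, len(primer) + 1):
        suf = primer[-k:]
        found = False
        for t in texts:
            for i in range(len(t) - k + 1):
                if t[i : i + k] == suf:
                    found = True
                    break
            if found:
                break
        if not found:
            break
        best = k
    return best


def f2_mutant_marker_fraction(r: float) -> float:
    """Fraction of mutant-phenotype F2 carrying the dominant marker, by
    enumerating the 4x4 gamete table of a repulsion-phase F1.

    F1 genotype: marker G and wild-type allele + on one homolog, no marker
    and recessive mutation m on the other.  Gametes: (G,+) and (-,m) at
    (1-r)/2 each; (G,m) and (-,+) at r/2 each.
    """
    gametes = [
        (True, False, (1 - r) / 2),   # G, wild-type
        (False, True, (1 - r) / 2),   # no marker, mutant
        (True, True, r / 2),
        (False, False, r / 2),
    ]
    mutant = 0.0
    mutant_marker = 0.0
    for g1, m1, p1 in gametes:
        for g2, m2, p2 in gametes:
            p = p1 * p2
            if m1 and m2:  # homozygous mutant phenotype
                mutant += p
                if g1 or g2:  # dominant marker
                    mutant_marker += p
    return mutant_marker / mutant
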