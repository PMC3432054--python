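"""Local-alignment specificity primitives used by the primer-design screen.

The screen mimics a blastn search of a candidate region against the
recipient genome: match +2, mismatch -3, gap of length k costing 5 + 2k
(existence 5, per-base extension 2), raw score, both strands.  Scores are
computed as exact Smith-Waterman optima (Biopython's C aligner), so the
raw-score cutoff has a precise meaning: a gapless stretch of >25 identical
bases on its own trips a cutoff of 50.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .genome import Genome


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5   # gap existence cost
    gap_extend: int = -2  # per gap base, including the first


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scheme.match
    al.mismatch_score = scheme.mismatch
    # Biopython charges open for the first gap base and extend thereafter;
    # translate so a length-k gap costs -(|open| + |extend| * k).
    al.open_gap_score = scheme.gap_open + scheme.gap_extend
    al.extend_gap_score = scheme.gap_extend
    return al


DEFAULT_SCHEME = ScoringScheme()


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def max_local_alignment_score(
    query: str,
    subject_genome: Genome | str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> int:
    """Maximum Smith-Waterman raw score of ``query`` against any subject
    location, on either strand.  Never negative (the empty alignment scores 0).
    """
    if not query:
        raise ValueError("empty query")
    subjects = (
        [c.sequence for c in subject_genome.chromosomes if c.sequence]
        if isinstance(subject_genome, Genome)
        else [subject_genome]
    )
    al = _make_aligner(scheme)
    q_fwd = query.upper()
    q_rev = reverse_complement(q_fwd)
    best = 0.0
    for s in subjects:
        if not s:
            continue
        best = max(best, al.score(s, q_fwd), al.score(s, q_rev))
    return int(round(best))


def region_is_species_specific(
    region_seq: str,
    recipient: Genome | str,
    cutoff: int = 50,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> bool:
    """True iff no recipient hit scores above ``cutoff`` (a score equal to
    the cutoff is retained; only strictly greater scores reject)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return max_local_alignment_score(region_seq, recipient, scheme) <= cutoff


def longest_three_prime_match(primer: str, recipient: Genome | str) -> int:
    """Length of the longest primer 3'-suffix occurring exactly anywhere in
    the recipient (either strand).

    Monotone in the suffix length (a shorter 3'-suffix is a substring of any
    longer one), so the answer is found by extending from the 3' end until
    the suffix disappears from the genome.
    """
    if not primer:
        raise ValueError("empty primer")
    primer = primer.upper()
    if isinstance(recipient, Genome):
        seqs = [c.sequence for c in recipient.chromosomes if c.sequence]
    else:
        seqs = [recipient]
    # one search text per strand; 'N' separators prevent cross-record matches
    text = "N".join(seqs)
    text = text + "N" + reverse_complement(text)
    k = 0
    while k < len(primer):
        if primer[len(primer) - k - 1 :] not in text:
            break
        k += 1
    return k


def primer_passes_three_prime_filter(
    primer: str, recipient: Genome | str, cutoff_bp: int = 8
) -> bool:
    """True iff the longest exact 3'-anchored recipient match is at most
    ``cutoff_bp`` bases (more than ``cutoff_bp`` rejects)."""
    if cutoff_bp < 0:
        raise ValueError("cutoff_bp must be >= 0")
    return longest_three_prime_match(primer, recipient) <= cutoff_bp
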