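"""In-silico single-worm PCR and the hierarchical genotyping strategy.

Two PCR modes are provided and kept deliberately consistent:

* coordinate mode — a pair calls positive on an individual iff at least one
  haplotype of the pair's chromosome carries a single donor-ancestry
  segment covering both primer binding intervals (heterozygous suffices;
  a physical template must be contiguous, so trans configurations and
  junction-split templates never amplify);
* sequence mode — a pair amplifies a sequence template iff a facing pair of
  binding sites exists within a product-size bound.  A binding site is an
  exact match of the primer's 3'-terminal core (15 nt) with at most two
  mismatches over the rest of the primer.  This simplified hybridisation
  rule is the single place the two modes could diverge, so it is
  centralised here and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .alignment import reverse_complement
from .cross import Individual
from .genome import Genome
from .panel import ARM_LABELS, PrimerPair
from .synthetic import SisterPair


# ---------------------------------------------------------------------------
# PCR, coordinate mode
# ---------------------------------------------------------------------------


def insilico_pcr_coordinate(ind: Individual, pair: PrimerPair) -> bool:
    """Presence/absence call for one primer pair on one individual."""
    haps = ind.haplotypes.get(pair.chrom)
    if haps is None:
        raise KeyError(f"individual has no chromosome {pair.chrom!r}")
    # both binding intervals lie inside [left_start, right_end), so one donor
    # segment covering the whole amplicon covers both primers
    return any(h.covers_with_donor(pair.left_start, pair.right_end) for h in haps)


# ---------------------------------------------------------------------------
# PCR, sequence mode
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingRule:
    core_bp: int = 15          # 3'-terminal bases requiring an exact match
    max_mismatches: int = 2    # tolerated in the remainder of the primer


DEFAULT_BINDING = BindingRule()


def _forward_sites(template: str, primer: str, rule: BindingRule) -> list[int]:
    """Start positions where the primer anneals to the plus strand pointing
    rightwards (its 3' core matching template exactly)."""
    core = primer[-rule.core_bp :] if len(primer) > rule.core_bp else primer
    tail = primer[: -len(core)] if len(primer) > len(core) else ""
    sites = []
    at = template.find(core)
    while at != -1:
        start = at - len(tail)
        if start >= 0:
            mm = sum(a != b for a, b in zip(tail, template[start:at]))
            if mm <= rule.max_mismatches:
                sites.append(start)
        at = template.find(core, at + 1)
    return sites


def _reverse_sites(template: str, primer: str, rule: BindingRule) -> list[int]:
    """End positions (half-open) where the primer anneals to the minus
    strand pointing leftwards."""
    rc = reverse_complement(primer)
    core = rc[: rule.core_bp] if len(rc) > rule.core_bp else rc
    tail = rc[len(core) :]
    sites = []
    at = template.find(core)
    while at != -1:
        end = at + len(core) + len(tail)
        if end <= len(template):
            mm = sum(a != b for a, b in zip(tail, template[at + len(core) : end]))
            if mm <= rule.max_mismatches:
                sites.append(end)
        at = template.find(core, at + 1)
    return sites


def insilico_pcr_sequence(
    template: Genome | str,
    pair: PrimerPair,
    max_product_bp: int = 2000,
    rule: BindingRule = DEFAULT_BINDING,
) -> tuple[bool, Optional[int]]:
    """Amplification call and smallest product size against raw sequence.

    Both primer orientations are tried, so an amplicon on either strand is
    found.  Records without sequence are skipped.
    """
    if isinstance(template, Genome):
        seqs = [c.sequence for c in template.chromosomes if c.sequence]
    else:
        seqs = [template]
    best: Optional[int] = None
    for seq in seqs:
        seq = seq.upper()
        for fwd, rev in ((pair.left_seq, pair.right_seq), (pair.right_seq, pair.left_seq)):
            starts = _forward_sites(seq, fwd.upper(), rule)
            if not starts:
                continue
            ends = _reverse_sites(seq, rev.upper(), rule)
            for s in starts:
                for e in ends:
                    size = e - s
                    if len(fwd) + len(rev) <= size <= max_product_bp:
                        best = size if best is None else min(best, size)
    return best is not None, best


def render_individual(ind: Individual, pair: SisterPair) -> Genome:
    """Realise an individual's haplotypes as sequence (one FASTA record per
    haplotype), splicing donor and recipient sequence at ancestry junctions.

    Donor segments contribute donor sequence at their own coordinates;
    recipient segments contribute the homologous recipient sequence located
    through the generator's coordinate map (indels make the two coordinate
    systems differ).
    """
    from .genome import Chromosome

    chroms = []
    for name, haps in ind.haplotypes.items():
        dseq = pair.donor[name].sequence
        rseq = pair.recipient[name].sequence
        if dseq is None or rseq is None:
            raise ValueError(f"{name}: sequences required to render an individual")
        for i, h in enumerate(haps):
            parts = []
            for seg in h.segments:
                if seg.origin == "donor":
                    parts.append(dseq[seg.start : seg.end])
                else:
                    r0 = pair.homology.donor_to_recipient(name, seg.start)
                    r1 = (
                        pair.homology.donor_to_recipient(name, seg.end - 1) + 1
                        if seg.end < h.length
                        else len(rseq)
                    )
                    parts.append(rseq[r0:r1])
            seq = "".join(parts)
            chroms.append(Chromosome(f"{name}_h{i}", len(seq), seq, is_sex=False))
    return Genome(f"individual_g{ind.generation}", chroms)


# ---------------------------------------------------------------------------
# genotype patterns and the hierarchical strategy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    primer_id: str
    chrom: str
    coordinate: int  # pair midpoint on the donor assembly
    call: bool


@dataclass
class GenotypePattern:
    entries: list[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda c: (c.chrom, c.coordinate))

    def on(self, chrom: str) -> "GenotypePattern":
        return GenotypePattern([c for c in self.entries if c.chrom == chrom])

    def positives(self) -> list[GenotypeCall]:
        return [c for c in self.entries if c.call]

    def chroms(self) -> list[str]:
        return sorted({c.chrom for c in self.entries})


def genotype_individual(
    ind: Individual, panel: list[PrimerPair], retained_only: bool = True
) -> GenotypePattern:
    """Run the whole panel (coordinate mode) on one individual."""
    calls = [
        GenotypeCall(p.id, p.chrom, p.midpoint, insilico_pcr_coordinate(ind, p))
        for p in panel
        if (not retained_only or p.status == "retained") and p.chrom in ind.haplotypes
    ]
    return GenotypePattern(calls)


@dataclass
class HierarchicalResult:
    assigned_chrom: Optional[str]
    multi_chrom: tuple[str, ...]  # all positive chromosomes when > 1
    pattern: GenotypePattern
    reactions_used: int


def _arm_representatives(pairs: list[PrimerPair]) -> list[PrimerPair]:
    """One pair per arm label, the median of its group: a representative
    near the arm's center catches a mid-arm segment that an edge pair would
    miss."""
    reps = []
    for label in ARM_LABELS:
        group = sorted((p for p in pairs if p.arm_label == label),
                       key=lambda p: p.midpoint)
        if group:
            reps.append(group[len(group) // 2])
    return reps


def hierarchical_genotype(
    ind: Individual,
    panel: list[PrimerPair],
    x_linked_known: bool = False,
    x_chrom: str = "X",
) -> HierarchicalResult:
    """Two-stage genotyping economising single-worm PCR reactions.

    Stage 1 runs one left + one middle + one right pair on each autosome
    (3 x 5 = 15 reactions with the default karyotype); stage 2 runs the
    remaining pairs of the implicated chromosome, so an autosomal marker
    with an n-pair chromosome panel costs 15 + (n - 3) reactions.  When the
    X linkage is already known from the crossing scheme, only the full X
    panel is run.  Positives on several chromosomes are reported as a flag,
    not an error (they flag assembly anomalies or co-segregating modifiers).
    """
    by_chrom: dict[str, list[PrimerPair]] = {}
    for p in panel:
        if p.status in ("retained", "candidate") and p.chrom in ind.haplotypes:
            by_chrom.setdefault(p.chrom, []).append(p)
    calls: list[GenotypeCall] = []
    reactions = 0

    def run(pairs: list[PrimerPair]) -> bool:
        nonlocal reactions
        any_pos = False
        for p in pairs:
            call = insilico_pcr_coordinate(ind, p)
            calls.append(GenotypeCall(p.id, p.chrom, p.midpoint, call))
            reactions += 1
            any_pos |= call
        return any_pos

    if x_linked_known:
        pairs = by_chrom.get(x_chrom, [])
        pos = run(pairs)
        assigned = x_chrom if pos else None
        return HierarchicalResult(assigned, (), GenotypePattern(calls), reactions)

    autosomes = [c for c in by_chrom if c != x_chrom]
    positive_chroms = []
    for chrom in autosomes:
        if run(_arm_representatives(by_chrom[chrom])):
            positive_chroms.append(chrom)
    if not positive_chroms:
        # X fallback: three representative X reactions, then the full X panel
        x_pairs = by_chrom.get(x_chrom, [])
        if x_pairs and run(_arm_representatives(x_pairs)):
            positive_chroms = [x_chrom]
    if not positive_chroms:
        return HierarchicalResult(None, (), GenotypePattern(calls), reactions)
    done = {c.primer_id for c in calls}
    for chrom in positive_chroms:
        run([p for p in by_chrom[chrom] if p.id not in done])
    multi = tuple(positive_chroms) if len(positive_chroms) > 1 else ()
    return HierarchicalResult(
        positive_chroms[0], multi, GenotypePattern(calls), reactions
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_pattern(pattern: GenotypePattern, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"primer_id": c.primer_id, "chrom": c.chrom,
             "coordinate": c.coordinate, "call": int(c.call)}
            for c in pattern.entries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pattern(path: str | Path) -> GenotypePattern:
    df = pd.read_csv(path, sep="\t")
    return GenotypePattern(
        [
            GenotypeCall(str(r.primer_id), str(r.chrom), int(r.coordinate), bool(r.call))
            for r in df.itertuples()
        ]
    )
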