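"""Species-specific primer panel design.

Implements the selection loop used to build a genotyping panel that
amplifies the donor genome but not the recipient: lay out evenly spaced,
arm-biased targets along each chromosome; around each target pick a
candidate region lying wholly in intronic/intergenic sequence and clear of
annotated repeats; reject regions with a recipient local-alignment raw
score above 50; pick a primer pair in the region; reject primers whose
3'-terminal sequence matches the recipient exactly for more than 8 bases;
on any failure re-select a nearby region and iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .alignment import (
    DEFAULT_SCHEME,
    ScoringScheme,
    longest_three_prime_match,
    max_local_alignment_score,
    primer_passes_three_prime_filter,
    region_is_species_specific,
)
from .genome import AnnotationSet, Genome, GenomeError

ARM_LABELS = ("left", "middle", "right")


class RegionExhaustedError(GenomeError):
    """No qualifying candidate region within the allowed search radius."""


class PanelInfeasibleError(GenomeError):
    """A chromosome yielded fewer retained primer pairs than required."""


@dataclass
class PrimerPair:
    id: str
    chrom: str
    left_seq: str
    right_seq: str
    left_start: int   # 0-based start of the left primer on the donor
    right_end: int    # 0-based half-open end of the right primer
    product_size_bp: int
    arm_label: str = "middle"
    status: str = "candidate"  # candidate | retained | discarded
    max_offtarget_score: int = -1
    max_three_prime_match: int = -1
    discard_cause: str = ""

    def __post_init__(self) -> None:
        if self.left_start >= self.right_end:
            raise GenomeError(f"{self.id}: left_start must precede right_end")
        if self.product_size_bp != self.right_end - self.left_start:
            raise GenomeError(f"{self.id}: product size inconsistent with coordinates")

    @property
    def midpoint(self) -> int:
        return (self.left_start + self.right_end) // 2


@dataclass
class PanelSpec:
    primers_per_chromosome: int = 15
    arm_density_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    candidate_region_length_bp: int = 500
    max_reselection_steps: int = 50
    reselection_step_bp: int = 1000
    offtarget_score_cutoff: int = 50
    three_prime_cutoff_bp: int = 8
    product_size_range: tuple[int, int] = (150, 800)
    primer_length_range: tuple[int, int] = (18, 27)
    tm_range_c: tuple[float, float] = (55.0, 62.0)
    gc_range: tuple[float, float] = (0.35, 0.65)
    max_homopolymer_run: int = 4
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.offtarget_score_cutoff <= 0 or self.three_prime_cutoff_bp < 0:
            raise ValueError("cutoffs must be positive")
        w = np.asarray(self.arm_density_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("arm weights must be non-negative and sum > 0")
        self.arm_density_weights = tuple(w / w.sum())


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------


def _allowed_intervals(
    annotation: AnnotationSet, chrom: str, chrom_length: int
) -> list[tuple[int, int]]:
    """Intervals usable for primer targets: non-exonic sequence minus repeats."""
    exons = sorted((f.start, f.end) for f in annotation.on(chrom, "exon"))
    repeats = sorted((f.start, f.end) for f in annotation.on(chrom, "repeat"))
    blocked = sorted(exons + repeats)
    merged: list[list[int]] = []
    for s, e in blocked:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    allowed: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            allowed.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_length:
        allowed.append((cursor, chrom_length))
    return allowed


def select_candidate_region(
    annotation: AnnotationSet,
    chrom: str,
    target_pos: int,
    spec: PanelSpec,
    chrom_length: int,
    exclude: Optional[set[tuple[int, int]]] = None,
) -> tuple[int, int]:
    """Nearest window of ``candidate_region_length_bp`` lying wholly in
    intron/intergenic sequence and overlapping no repeat.

    The search alternates outward from the target in steps of
    ``reselection_step_bp`` up to ``max_reselection_steps`` (previously
    tried windows can be excluded so that repeated calls walk to the next
    nearest alternative).
    """
    if not 0 <= target_pos < chrom_length:
        raise GenomeError(f"target {target_pos} outside {chrom} [0, {chrom_length})")
    W = spec.candidate_region_length_bp
    exclude = exclude or set()
    radius = spec.max_reselection_steps * spec.reselection_step_bp
    candidates: list[tuple[int, int, int]] = []  # (distance, start, end)
    for s, e in _allowed_intervals(annotation, chrom, chrom_length):
        if e - s < W:
            continue
        # placement closest to the target inside this interval ...
        start = min(max(target_pos - W // 2, s), e - W)
        placements = {start}
        # ... plus a coarse grid so re-selection has distinct alternatives
        g = s
        while g + W <= e:
            placements.add(g)
            g += spec.reselection_step_bp
        for p in placements:
            center = p + W // 2
            dist = abs(center - target_pos)
            if dist <= radius and (p, p + W) not in exclude:
                candidates.append((dist, p, p + W))
    if not candidates:
        raise RegionExhaustedError(
            f"{chrom}: no candidate region within {radius} bp of {target_pos}"
        )
    candidates.sort()
    _, s, e = candidates[0]
    return s, e


# ---------------------------------------------------------------------------
# primer picking
# ---------------------------------------------------------------------------


def _has_long_run(seq: str, max_run: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


def _primer_ok(seq: str, spec: PanelSpec) -> Optional[float]:
    """Melting temperature if the oligo satisfies all constraints, else None."""
    gc = gc_fraction(seq)
    if not spec.gc_range[0] <= gc <= spec.gc_range[1]:
        return None
    if _has_long_run(seq, spec.max_homopolymer_run):
        return None
    tm = MeltingTemp.Tm_NN(seq)
    if not spec.tm_range_c[0] <= tm <= spec.tm_range_c[1]:
        return None
    return tm


def _scan_primers(
    region: str, spec: PanelSpec, from_right: bool, limit: int = 25
) -> list[tuple[int, int, float]]:
    """Candidate (start, end, Tm) oligos anchored near one region end.

    Scans inward from the region boundary; for each start the shortest
    length whose Tm lands in the window is taken (Tm grows with length, so
    longer lengths at the same start are redundant).
    """
    lo, hi = spec.primer_length_range
    n = len(region)
    out: list[tuple[int, int, float]] = []
    for off in range(0, n - lo + 1):
        for length in range(lo, hi + 1):
            if from_right:
                end = n - off
                start = end - length
            else:
                start = off
                end = start + length
            if start < 0 or end > n:
                break
            tm = _primer_ok(region[start:end], spec)
            if tm is not None:
                out.append((start, end, tm))
                break
            # bail out once the oligo is already too hot: longer only gets hotter
            if MeltingTemp.Tm_NN(region[start:end]) > spec.tm_range_c[1]:
                break
        if len(out) >= limit:
            break
    return out


def pick_primer_pair(
    region_seq: str,
    spec: PanelSpec,
    region_start: int = 0,
    chrom: str = "",
    pair_id: str = "",
) -> Optional[PrimerPair]:
    """Best primer pair within a candidate region, or None.

    Constraints: length 18-27 nt, nearest-neighbor Tm 55-62 C, GC 35-65%,
    no homopolymer run over 4, product size within the spec range.  Ties are
    broken by the smallest pair Tm difference, then leftmost coordinate, so
    the result is deterministic for a fixed input.
    """
    from .alignment import reverse_complement

    min_prod, max_prod = spec.product_size_range
    if len(region_seq) < min_prod:
        return None
    region_seq = region_seq.upper()
    lefts = _scan_primers(region_seq, spec, from_right=False)
    rights = _scan_primers(region_seq, spec, from_right=True)
    best = None
    for ls, le, ltm in lefts:
        for rs, re_, rtm in rights:
            size = re_ - ls
            if size < min_prod or size > max_prod or le >= rs:
                continue
            key = (abs(ltm - rtm), ls, -re_)
            if best is None or key < best[0]:
                best = (key, ls, le, rs, re_, ltm, rtm)
    if best is None:
        return None
    _, ls, le, rs, re_, _, _ = best
    return PrimerPair(
        id=pair_id or f"{chrom}:{region_start + ls}",
        chrom=chrom,
        left_seq=region_seq[ls:le],
        right_seq=reverse_complement(region_seq[rs:re_]),
        left_start=region_start + ls,
        right_end=region_start + re_,
        product_size_bp=re_ - ls,
    )


# ---------------------------------------------------------------------------
# panel design
# ---------------------------------------------------------------------------


def _arm_label(midpoint: int, chrom_length: int) -> str:
    third = chrom_length / 3
    if midpoint < third:
        return "left"
    if midpoint < 2 * third:
        return "middle"
    return "right"


def layout_targets(chrom_length: int, spec: PanelSpec) -> list[int]:
    """Target positions per chromosome: counts per physical third follow the
    arm density weights (largest-remainder rounding), evenly spaced within
    each third."""
    n = spec.primers_per_chromosome
    w = np.asarray(spec.arm_density_weights, dtype=float)
    raw = w * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[order[i % 3]] += 1
    targets: list[int] = []
    third = chrom_length / 3
    for i, c in enumerate(counts):
        for j in range(c):
            targets.append(int(i * third + (j + 0.5) * third / c))
    return sorted(targets)


@dataclass
class PanelDesign:
    panel: list[PrimerPair]
    log: list[dict]

    def retained(self) -> list[PrimerPair]:
        return [p for p in self.panel if p.status == "retained"]


def design_panel(
    donor: Genome,
    recipient: Genome,
    annotation: AnnotationSet,
    gmap=None,
    spec: Optional[PanelSpec] = None,
    min_pairs_per_chromosome: int = 3,
    validate: bool = True,
) -> PanelDesign:
    """Run the full selection loop over every (non-contaminant) chromosome.

    Every rejection is logged with its cause.  When ``validate`` is true the
    finished panel is additionally in-silico amplified against both genomes
    and cross-amplifying pairs are discarded, so retained pairs amplify the
    donor only.
    """
    spec = spec or PanelSpec()
    panel: list[PrimerPair] = []
    log: list[dict] = []
    for chrom in donor.chromosomes:
        if chrom.is_contaminant:
            continue
        if chrom.sequence is None:
            raise GenomeError(f"{chrom.name}: sequence required for panel design")
        n_ok = 0
        for t_idx, target in enumerate(layout_targets(chrom.length_bp, spec)):
            pair = _design_one(
                chrom.name, chrom.sequence, target, annotation, recipient, spec, log
            )
            if pair is not None:
                pair.id = f"{chrom.name}-{t_idx + 1:02d}"
                pair.arm_label = _arm_label(pair.midpoint, chrom.length_bp)
                pair.status = "retained"
                panel.append(pair)
                n_ok += 1
        if n_ok < min_pairs_per_chromosome:
            raise PanelInfeasibleError(
                f"{chrom.name}: only {n_ok} primer pairs retained "
                f"(need >= {min_pairs_per_chromosome}); the genomes may be "
                "too similar for species-specific design"
            )
    design = PanelDesign(panel=panel, log=log)
    if validate:
        validate_panel(design.panel, donor, recipient)
    return design


def _design_one(
    chrom: str,
    donor_seq: str,
    target: int,
    annotation: AnnotationSet,
    recipient: Genome,
    spec: PanelSpec,
    log: list[dict],
) -> Optional[PrimerPair]:
    tried: set[tuple[int, int]] = set()
    for _ in range(spec.max_reselection_steps):
        try:
            region = select_candidate_region(
                annotation, chrom, target, spec, len(donor_seq), exclude=tried
            )
        except RegionExhaustedError:
            log.append({"chrom": chrom, "target": target, "cause": "region_exhausted"})
            return None
        tried.add(region)
        s, e = region
        region_seq = donor_seq[s:e]
        score = max_local_alignment_score(region_seq, recipient, spec.scoring)
        if score > spec.offtarget_score_cutoff:
            log.append(
                {"chrom": chrom, "target": target, "region": f"{s}-{e}",
                 "cause": "conserved_region", "score": score}
            )
            continue
        pair = pick_primer_pair(region_seq, spec, region_start=s, chrom=chrom)
        if pair is None:
            log.append(
                {"chrom": chrom, "target": target, "region": f"{s}-{e}",
                 "cause": "no_primer"}
            )
            continue
        m3 = max(
            longest_three_prime_match(pair.left_seq, recipient),
            longest_three_prime_match(pair.right_seq, recipient),
        )
        if m3 > spec.three_prime_cutoff_bp:
            log.append(
                {"chrom": chrom, "target": target, "region": f"{s}-{e}",
                 "cause": "three_prime_match", "match_bp": m3}
            )
            continue
        pair.max_offtarget_score = score
        pair.max_three_prime_match = m3
        return pair
    log.append({"chrom": chrom, "target": target, "cause": "steps_exhausted"})
    return None


# ---------------------------------------------------------------------------
# validation and summary statistics
# ---------------------------------------------------------------------------


@dataclass
class PanelValidation:
    n_candidates: int
    n_cross_amplifying: int
    n_no_donor_product: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_candidates - self.n_cross_amplifying - self.n_no_donor_product


def validate_panel(
    panel: list[PrimerPair],
    donor: Genome,
    recipient: Genome,
    max_product_bp: int = 2000,
) -> PanelValidation:
    """In-silico amplify every pair against both genomes (sequence mode) and
    discard the cross-amplifiers: retained = candidates - cross-amplifying.
    """
    from .pcr import insilico_pcr_sequence

    if not panel:
        raise ValueError("empty panel")
    n_cross = 0
    n_nodonor = 0
    for pair in panel:
        ok_donor, _ = insilico_pcr_sequence(donor, pair, max_product_bp)
        ok_recip, _ = insilico_pcr_sequence(recipient, pair, max_product_bp)
        if ok_recip:
            pair.status = "discarded"
            pair.discard_cause = "cross_amplifying"
            n_cross += 1
        elif not ok_donor:
            pair.status = "discarded"
            pair.discard_cause = "no_donor_product"
            n_nodonor += 1
        else:
            pair.status = "retained"
    return PanelValidation(len(panel), n_cross, n_nodonor)


def panel_spacing_stats(panel: list[PrimerPair], genome: Genome) -> pd.DataFrame:
    """Adjacent-gap statistics between consecutive retained pairs.

    Gaps are measured between pair midpoints; chromosomes with fewer than
    two retained pairs are omitted with a warning.  The global mean appears
    as the row with chrom '*'.
    """
    rows = []
    all_gaps: list[int] = []
    for chrom in genome.names:
        pts = sorted(p.midpoint for p in panel if p.chrom == chrom and p.status == "retained")
        if len(pts) < 2:
            if any(p.chrom == chrom for p in panel):
                warnings.warn(f"{chrom}: fewer than 2 retained pairs; omitted")
            continue
        gaps = np.diff(pts)
        all_gaps.extend(gaps.tolist())
        rows.append(
            {"chrom": chrom, "n_pairs": len(pts),
             "mean_gap_bp": float(gaps.mean()), "max_gap_bp": int(gaps.max())}
        )
    if all_gaps:
        rows.append(
            {"chrom": "*", "n_pairs": sum(r["n_pairs"] for r in rows),
             "mean_gap_bp": float(np.mean(all_gaps)), "max_gap_bp": int(max(all_gaps))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "id", "chrom", "left_start", "right_end", "product_size_bp", "arm_label",
    "status", "left_seq", "right_seq", "max_offtarget_score",
    "max_three_prime_match", "discard_cause",
]


def write_panel(panel: list[PrimerPair], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(p, c) for c in _TSV_COLUMNS} for p in panel])
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PrimerPair(
            id=str(r["id"]), chrom=str(r["chrom"]),
            left_seq=str(r["left_seq"]), right_seq=str(r["right_seq"]),
            left_start=int(r["left_start"]), right_end=int(r["right_end"]),
            product_size_bp=int(r["product_size_bp"]), arm_label=str(r["arm_label"]),
            status=str(r["status"]),
            max_offtarget_score=int(r["max_offtarget_score"]),
            max_three_prime_match=int(r["max_three_prime_match"]),
            discard_cause=str(r["discard_cause"]),
        )
        for _, r in df.iterrows()
    ]


def write_panel_bed(panel: list[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in panel:
            fh.write(
                f"{p.chrom}\t{p.left_start}\t{p.left_start + len(p.left_seq)}\t{p.id}_L\t0\t+\n"
            )
            fh.write(
                f"{p.chrom}\t{p.right_end - len(p.right_seq)}\t{p.right_end}\t{p.id}_R\t0\t-\n"
            )
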