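"""Interval and size inference from presence/absence genotype patterns,
discontinuity detection, and two-point F2 linkage estimation.

The marker locus lies between the boundaries defined by its two adjacent
primer pairs: the *inner* interval spans the outermost positive primers
(the reported introgression size), and the *outer* interval extends to the
nearest flanking negative primers (or the chromosome ends), bracketing the
true insertion site with certainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .genome import GenomeError, format_mb
from .pcr import GenotypePattern


class NoPositiveCallsError(GenomeError):
    """A pattern with no positive call defines no interval."""


@dataclass
class IntrogressionInterval:
    chrom: str
    inner_start: int  # outermost positive primer coordinates
    inner_end: int
    outer_start: int  # nearest flanking negative primers (or chromosome ends)
    outer_end: int

    def __post_init__(self) -> None:
        if not self.outer_start <= self.inner_start <= self.inner_end <= self.outer_end:
            raise GenomeError("interval bounds out of order")

    @property
    def size_bp(self) -> int:
        """Reported introgression size: the outermost-positive span."""
        return self.inner_end - self.inner_start

    @property
    def bracket_size_bp(self) -> int:
        return self.outer_end - self.outer_start

    def describe(self) -> str:
        return (
            f"{self.chrom}: {format_mb(self.inner_start)} to "
            f"{format_mb(self.inner_end)} Mb ({format_mb(self.size_bp)} Mb)"
        )


def _single_chrom(pattern: GenotypePattern) -> str:
    chroms = pattern.chroms()
    if len(chroms) != 1:
        raise GenomeError(f"pattern must cover one chromosome, got {chroms}")
    return chroms[0]


def infer_interval(pattern: GenotypePattern, chrom_length: int) -> IntrogressionInterval:
    """Interval implied by a single-chromosome presence/absence pattern."""
    chrom = _single_chrom(pattern)
    pos = [c.coordinate for c in pattern.entries if c.call]
    if not pos:
        raise NoPositiveCallsError(f"{chrom}: no positive call in pattern")
    inner_start, inner_end = min(pos), max(pos)
    below = [c.coordinate for c in pattern.entries if not c.call and c.coordinate < inner_start]
    above = [c.coordinate for c in pattern.entries if not c.call and c.coordinate > inner_end]
    return IntrogressionInterval(
        chrom=chrom,
        inner_start=inner_start,
        inner_end=inner_end,
        outer_start=max(below) if below else 0,
        outer_end=min(above) if above else chrom_length,
    )


def detect_segments(
    pattern: GenotypePattern, chrom_length: int
) -> list[IntrogressionInterval]:
    """Split a pattern into maximal runs of consecutive positive calls.

    A single negative call between positives separates two intervals —
    the signature of a discontinuous introgression (or of an assembly
    anomaly worth reporting).
    """
    chrom = _single_chrom(pattern)
    out: list[IntrogressionInterval] = []
    entries = pattern.entries
    i = 0
    while i < len(entries):
        if not entries[i].call:
            i += 1
            continue
        j = i
        while j + 1 < len(entries) and entries[j + 1].call:
            j += 1
        out.append(
            IntrogressionInterval(
                chrom=chrom,
                inner_start=entries[i].coordinate,
                inner_end=entries[j].coordinate,
                outer_start=entries[i - 1].coordinate if i > 0 else 0,
                outer_end=entries[j + 1].coordinate if j + 1 < len(entries) else chrom_length,
            )
        )
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# two-point linkage from F2 segregation
# ---------------------------------------------------------------------------


@dataclass
class LinkageResult:
    r_hat: float
    n_mutant_gfp_pos: int
    n_mutant_gfp_neg: int


def expected_f2_mutant_gfp_fraction(r: float) -> float:
    """Fraction of mutant-phenotype F2 that carry the dominant marker.

    Repulsion-phase F1 (marker from one parent, recessive visible mutation
    from the other) selfed or intercrossed: a mutant offspring received an
    m-bearing gamete from each parent, and each such gamete carries the
    marker with probability r, so the marker-positive fraction among
    mutants is 1 - (1 - r)^2 = 2r - r^2.  Unlinked loci (r = 1/2) give the
    familiar 3/4.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5]")
    return 2 * r - r * r


def estimate_recombination(n_pos: int, n_neg: int) -> LinkageResult:
    """Invert the F2 segregation ratio: r_hat = 1 - sqrt(n_neg / n_total),
    clipped to [0, 0.5]."""
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg == 0:
        raise ValueError("need non-negative counts with a positive total")
    r = 1.0 - math.sqrt(n_neg / (n_pos + n_neg))
    return LinkageResult(min(max(r, 0.0), 0.5), n_pos, n_neg)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def interval_report(
    rows: list[tuple[str, IntrogressionInterval]], path: Optional[str | Path] = None
) -> pd.DataFrame:
    """Summary table: strain, linkage group, physical position 'A to B Mb',
    introgression size in Mb (one decimal)."""
    df = pd.DataFrame(
        [
            {
                "strain": strain,
                "linkage_group": f"Chrom {iv.chrom}",
                "physical_position": f"{format_mb(iv.inner_start)} to "
                f"{format_mb(iv.inner_end)} Mb",
                "introgression_size": f"{format_mb(iv.size_bp)} Mb",
                "bracket_size": f"{format_mb(iv.bracket_size_bp)} Mb",
            }
            for strain, iv in rows
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_intervals_bed(
    rows: list[tuple[str, IntrogressionInterval]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for strain, iv in rows:
            fh.write(f"{iv.chrom}\t{iv.inner_start}\t{iv.inner_end}\t{strain}_inner\n")
            fh.write(f"{iv.chrom}\t{iv.outer_start}\t{iv.outer_end}\t{strain}_outer\n")
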