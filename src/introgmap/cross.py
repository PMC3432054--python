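"""Backcross introgression simulation with junction/segment ancestry.

A hybrid carrier of a dominant visible marker is crossed repeatedly to the
pure recipient species; each generation a marker-positive offspring (of the
sex the scheme requires) is selected.  Haplotypes are ordered lists of
donor/recipient ancestry segments in donor physical coordinates; crossovers
are drawn in genetic coordinates and mapped to physical positions through
the genetic map, so the arm/center recombination asymmetry is honoured
without a map-function transformation.

Two crossover models are available.  ``obligate_single`` (default) places
exactly one crossover on the bivalent per meiosis, with the transmitted
chromatid recombinant with probability 1/2 — the near-complete interference
regime of Caenorhabditis meiosis.  ``poisson`` draws a Poisson number of
crossovers per transmitted gamete (rate one per Morgan, no interference),
whose marker-flank retention has the closed form (1 - e^{-t d}) / t and so
serves as the analytically checkable alternative.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .genome import GeneticMap, Genome, GenomeError, MarkerLocus

DONOR = "donor"
RECIPIENT = "recipient"

Origin = Literal["donor", "recipient"]


class BroodExhaustedError(RuntimeError):
    """No marker-positive offspring of the required sex in the brood."""


@dataclass(frozen=True)
class AncestrySegment:
    start: int
    end: int
    origin: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError("segment start must precede end")


@dataclass
class Haplotype:
    chrom: str
    segments: list[AncestrySegment]

    @staticmethod
    def uniform(chrom: str, length: int, origin: str) -> "Haplotype":
        return Haplotype(chrom, [AncestrySegment(0, length, origin)])

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def origin_at(self, pos: int) -> str:
        for seg in self.segments:
            if seg.start <= pos < seg.end:
                return seg.origin
        raise GenomeError(f"position {pos} outside haplotype [0, {self.length})")

    def donor_bp(self) -> int:
        return sum(s.end - s.start for s in self.segments if s.origin == DONOR)

    def donor_segment_containing(self, pos: int) -> Optional[AncestrySegment]:
        for seg in self.segments:
            if seg.origin == DONOR and seg.start <= pos < seg.end:
                return seg
        return None

    def covers_with_donor(self, start: int, end: int) -> bool:
        """True iff one donor segment covers [start, end) entirely."""
        return any(
            s.origin == DONOR and s.start <= start and end <= s.end
            for s in self.segments
        )

    def canonical(self) -> "Haplotype":
        """Merge adjacent same-origin segments; validate exact tiling."""
        if not self.segments:
            raise GenomeError("empty haplotype")
        merged: list[AncestrySegment] = []
        expected = 0
        for seg in self.segments:
            if seg.start != expected:
                raise GenomeError(
                    f"{self.chrom}: segments do not tile (gap/overlap at {seg.start})"
                )
            expected = seg.end
            if merged and merged[-1].origin == seg.origin:
                merged[-1] = AncestrySegment(merged[-1].start, seg.end, seg.origin)
            else:
                merged.append(seg)
        return Haplotype(self.chrom, merged)


@dataclass
class Individual:
    sex: str  # female | male
    haplotypes: dict[str, list[Haplotype]]  # chrom -> 1 or 2 haplotypes
    marker: MarkerLocus
    generation: int = 0
    x_chrom: Optional[str] = None  # name of the sex chromosome, if any

    def is_marker_positive(self) -> bool:
        return any(
            h.donor_segment_containing(self.marker.position_bp) is not None
            for h in self.haplotypes.get(self.marker.chrom, [])
        )


@dataclass
class CrossScheme:
    linkage: str = "autosomal"  # autosomal | x_linked
    large_x_effect: bool = False
    generations: int = 8  # number of backcross rounds after the F1
    brood_size: int = 20
    crossover_model: str = "obligate_single"  # obligate_single | poisson
    seed: int = 0
    recipient_label: str = "recipient"

    def __post_init__(self) -> None:
        if self.generations < 1 or self.brood_size < 1:
            raise ValueError("generations and brood_size must be >= 1")
        if self.linkage not in ("autosomal", "x_linked"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.crossover_model not in ("obligate_single", "poisson"):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")


class RngStreams:
    """Independent per-chromosome random streams keyed by chromosome name,
    so reordering chromosomes cannot change any chromosome's draws."""

    def __init__(self, seed: int):
        self.seed = int(seed) & 0x7FFFFFFF
        self._streams: dict[str, np.random.Generator] = {}

    def for_chrom(self, name: str) -> np.random.Generator:
        if name not in self._streams:
            self._streams[name] = np.random.default_rng(
                [self.seed, zlib.crc32(name.encode())]
            )
        return self._streams[name]


def _required_sex(scheme: CrossScheme, next_generation: int) -> Optional[str]:
    """Sex the scheme demands of the selected carrier for the next cross.

    Autosomal introgression selects any marker-positive carrier.  X-linked
    with the large-X effect (marker-positive males rare/sterile) selects
    females only; without it the crossing direction alternates by
    generation parity.
    """
    if scheme.linkage == "autosomal":
        return None
    if scheme.large_x_effect:
        return "female"
    return "male" if next_generation % 2 == 0 else "female"


def make_f1(
    donor: Genome, recipient: Genome, marker: MarkerLocus, scheme: CrossScheme
) -> Individual:
    """The F1 female from a donor-male x recipient-female cross.

    Heterozygous genome-wide: each autosome pairs one all-donor with one
    all-recipient haplotype; the X pairs the father's donor X with the
    mother's recipient X.  Hybrid F1 males are inviable/sterile and are not
    modelled.  Coordinates are the donor's (focal) physical coordinates.
    """
    if marker.chrom not in donor:
        raise GenomeError(f"marker chromosome {marker.chrom!r} not in donor")
    haps: dict[str, list[Haplotype]] = {}
    x_chrom = None
    for c in donor.chromosomes:
        if c.is_contaminant:
            continue
        if c.is_sex:
            x_chrom = c.name
        haps[c.name] = [
            Haplotype.uniform(c.name, c.length_bp, DONOR),
            Haplotype.uniform(c.name, c.length_bp, RECIPIENT),
        ]
    f1 = Individual(
        sex="female", haplotypes=haps, marker=marker, generation=1, x_chrom=x_chrom
    )
    if not f1.is_marker_positive():
        raise GenomeError("F1 does not carry the marker; check the marker locus")
    return f1


def _splice(ha: Haplotype, hb: Haplotype, cuts: list[int]) -> Haplotype:
    """Recombinant chromatid: ha up to the first cut, alternating thereafter."""
    L = ha.length
    sources = (ha, hb)
    out: list[AncestrySegment] = []
    bounds = [0] + sorted(cuts) + [L]
    cur = 0
    for lo, hi in zip(bounds, bounds[1:]):
        if lo >= hi:
            cur ^= 1
            continue
        for seg in sources[cur].segments:
            s, e = max(seg.start, lo), min(seg.end, hi)
            if s < e:
                out.append(AncestrySegment(s, e, seg.origin))
        cur ^= 1
    return Haplotype(ha.chrom, out).canonical()


def meiosis(
    parent: Individual,
    chrom: str,
    gmap: GeneticMap,
    model: str,
    rng: np.random.Generator,
) -> Haplotype:
    """One transmitted gamete haplotype for ``chrom``.

    Hemizygous chromosomes (male X) are transmitted without recombination.
    Crossover positions are drawn uniformly in genetic coordinates and
    mapped back to physical coordinates, so crossovers concentrate where
    the map is genetically dense (the arms).
    """
    try:
        pair = parent.haplotypes[chrom]
    except KeyError:
        raise GenomeError(f"chromosome {chrom!r} absent from parent") from None
    if len(pair) == 1:
        return pair[0].canonical()
    h0, h1 = pair
    map_len = gmap.map_length_cm(chrom)
    if model == "obligate_single":
        recombinant = rng.random() < 0.5
        a = int(rng.integers(2))
        if recombinant:
            cut_cm = float(rng.random()) * map_len
            cut = int(round(gmap.genetic_to_physical(chrom, cut_cm)))
            cuts = [cut] if 0 < cut < h0.length else []
        else:
            cuts = []
    elif model == "poisson":
        n = int(rng.poisson(map_len / 100.0))
        a = int(rng.integers(2))
        cuts_cm = sorted(float(x) * map_len for x in rng.random(n))
        cuts = [
            c
            for c in (int(round(gmap.genetic_to_physical(chrom, x))) for x in cuts_cm)
            if 0 < c < h0.length
        ]
    else:
        raise ValueError(f"unknown crossover model {model!r}")
    first, second = (h0, h1) if a == 0 else (h1, h0)
    return _splice(first, second, cuts)


def _make_offspring(
    carrier: Individual,
    scheme: CrossScheme,
    gmap: GeneticMap,
    streams: RngStreams,
) -> Individual:
    """One offspring of carrier x pure-recipient.

    Sex follows X transmission: XX female, X0 male.  The recipient parent
    contributes an all-recipient haplotype to every autosome; X inheritance
    depends on which parent carries the introgression.
    """
    marker = carrier.marker
    haps: dict[str, list[Haplotype]] = {}
    x_name = carrier.x_chrom
    for chrom, pair in carrier.haplotypes.items():
        if chrom == x_name:
            continue
        rng = streams.for_chrom(chrom)
        gamete = meiosis(carrier, chrom, gmap, scheme.crossover_model, rng)
        haps[chrom] = [gamete, Haplotype.uniform(chrom, gamete.length, RECIPIENT)]
    if x_name is not None:
        rng = streams.for_chrom(x_name)
        xlen = carrier.haplotypes[x_name][0].length
        if carrier.sex == "female":
            # father is a pure recipient male: X-bearing sperm -> daughter
            gamete = meiosis(carrier, x_name, gmap, scheme.crossover_model, rng)
            if rng.random() < 0.5:
                sex = "female"
                haps[x_name] = [gamete, Haplotype.uniform(x_name, xlen, RECIPIENT)]
            else:
                sex = "male"
                haps[x_name] = [gamete]
        else:
            # carrier is male: daughters get his X as-is, sons the mother's
            if rng.random() < 0.5:
                sex = "female"
                haps[x_name] = [
                    carrier.haplotypes[x_name][0].canonical(),
                    Haplotype.uniform(x_name, xlen, RECIPIENT),
                ]
            else:
                sex = "male"
                haps[x_name] = [Haplotype.uniform(x_name, xlen, RECIPIENT)]
    else:
        sex = "female" if streams.for_chrom("_sex").random() < 0.5 else "male"
    return Individual(
        sex=sex,
        haplotypes=haps,
        marker=marker,
        generation=carrier.generation + 1,
        x_chrom=x_name,
    )


def backcross_once(
    carrier: Individual,
    scheme: CrossScheme,
    gmap: GeneticMap,
    streams: RngStreams,
) -> Individual:
    """Cross the carrier to a pure recipient and select the first
    marker-positive offspring of the required sex from a brood."""
    if not carrier.is_marker_positive():
        raise BroodExhaustedError("carrier is marker-negative; nothing to select")
    want = _required_sex(scheme, carrier.generation + 1)
    for _ in range(scheme.brood_size):
        child = _make_offspring(carrier, scheme, gmap, streams)
        if child.is_marker_positive() and (want is None or child.sex == want):
            return child
    raise BroodExhaustedError(
        f"no marker-positive {want or 'any-sex'} offspring in a brood of "
        f"{scheme.brood_size} (generation {carrier.generation + 1})"
    )


@dataclass
class SegmentStats:
    generation: int
    marker_linked_bp: Optional[int]
    total_donor_bp: int
    donor_segments_per_chrom: dict[str, int] = field(default_factory=dict)


def segment_stats(ind: Individual) -> SegmentStats:
    """Marker-linked donor segment length, total donor content, and donor
    segment counts, for one individual."""
    marker = ind.marker
    linked = None
    for h in ind.haplotypes.get(marker.chrom, []):
        seg = h.canonical().donor_segment_containing(marker.position_bp)
        if seg is not None:
            linked = seg.end - seg.start if linked is None else max(linked, seg.end - seg.start)
    total = sum(h.donor_bp() for pair in ind.haplotypes.values() for h in pair)
    counts = {
        chrom: sum(
            sum(1 for s in h.canonical().segments if s.origin == DONOR) for h in pair
        )
        for chrom, pair in ind.haplotypes.items()
    }
    return SegmentStats(ind.generation, linked, total, counts)


@dataclass
class Trajectory:
    individuals: list[Individual]
    stats: list[SegmentStats]

    @property
    def final(self) -> Individual:
        return self.individuals[-1]


def run_introgression(
    donor: Genome,
    recipient: Genome,
    marker: MarkerLocus,
    scheme: CrossScheme,
    gmap: GeneticMap,
    max_brood_retries: int = 20,
) -> Trajectory:
    """F1 plus ``scheme.generations`` marker-selected backcrosses.

    Deterministic under a fixed scheme seed.  A brood with no acceptable
    offspring is simply re-drawn, up to ``max_brood_retries`` times per
    generation (each retry is a fresh brood from the same carrier).
    """
    gmap.validate_against(donor)
    streams = RngStreams(scheme.seed)
    f1 = make_f1(donor, recipient, marker, scheme)
    individuals = [f1]
    stats = [segment_stats(f1)]
    carrier = f1
    for _ in range(scheme.generations):
        last_err: Optional[BroodExhaustedError] = None
        for _retry in range(max_brood_retries):
            try:
                carrier = backcross_once(carrier, scheme, gmap, streams)
                last_err = None
                break
            except BroodExhaustedError as err:
                last_err = err
        if last_err is not None:
            raise last_err
        individuals.append(carrier)
        stats.append(segment_stats(carrier))
    return Trajectory(individuals, stats)


def write_individual(ind: Individual, path) -> None:
    """Serialise an individual as TSV: header comments carry sex, generation
    and marker; rows are (chrom, haplotype index, start, end, origin)."""
    with open(path, "w") as fh:
        fh.write(f"#sex={ind.sex}\n")
        fh.write(f"#generation={ind.generation}\n")
        fh.write(f"#marker={ind.marker.chrom}:{ind.marker.position_bp}:{ind.marker.label}\n")
        fh.write(f"#x_chrom={ind.x_chrom or ''}\n")
        fh.write("chrom\thaplotype\tstart\tend\torigin\n")
        for chrom in sorted(ind.haplotypes):
            for i, h in enumerate(ind.haplotypes[chrom]):
                for seg in h.segments:
                    fh.write(f"{chrom}\t{i}\t{seg.start}\t{seg.end}\t{seg.origin}\n")


def read_individual(path) -> Individual:
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k] = v
            elif line and not line.startswith("chrom\t"):
                chrom, hap, start, end, origin = line.split("\t")
                rows.append((chrom, int(hap), int(start), int(end), origin))
    mc, mp, ml = meta["marker"].split(":")
    haps: dict[str, list[Haplotype]] = {}
    for chrom, hap, start, end, origin in rows:
        lst = haps.setdefault(chrom, [])
        while len(lst) <= hap:
            lst.append(Haplotype(chrom, []))
        lst[hap].segments.append(AncestrySegment(start, end, origin))
    haps = {c: [h.canonical() for h in lst] for c, lst in haps.items()}
    return Individual(
        sex=meta["sex"],
        haplotypes=haps,
        marker=MarkerLocus(mc, int(mp), ml),
        generation=int(meta["generation"]),
        x_chrom=meta.get("x_chrom") or None,
    )


def expected_flank_length(t: int, flank_morgans: float) -> float:
    """Expected retained donor length (Morgans) on one marker flank after
    ``t`` marker-selected backcross meioses, under crossovers arriving at
    rate one per Morgan per meiosis with no interference:

        E[L] = (1 - exp(-t * d)) / t,   d = flank length in Morgans.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if flank_morgans < 0:
        raise ValueError("flank must be non-negative")
    if flank_morgans == 0:
        return 0.0
    return (1.0 - math.exp(-t * flank_morgans)) / t
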