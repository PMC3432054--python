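"""Core data model: genomes, annotation, genetic maps, and standard-format I/O.

Coordinates are 0-based half-open internally everywhere.  GFF3 (1-based,
closed) is converted at the I/O boundary; BED is passed through.  User-facing
reports print 1-based inclusive positions and megabases with one decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("exon", "intron", "intergenic", "repeat")

#: default demo karyotype: five autosomes plus X, matching the focal species
DEFAULT_CHROM_NAMES = ("I", "II", "III", "IV", "V", "X")


class GenomeError(ValueError):
    """Raised on malformed genomes, annotation, or map files."""


@dataclass
class Chromosome:
    """One chromosome: a name, a length, and (optionally) its sequence.

    ``sequence`` may be ``None`` for coordinate-only work (introgression
    simulation does not need bases, only lengths and the genetic map).
    """

    name: str
    length_bp: int
    sequence: Optional[str] = None
    is_sex: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise GenomeError(f"chromosome {self.name!r}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise GenomeError(
                f"chromosome {self.name!r}: sequence length "
                f"{len(self.sequence)} != length_bp {self.length_bp}"
            )


@dataclass
class MarkerLocus:
    """A dominant, visible marker (e.g. an integrated GFP cassette)."""

    chrom: str
    position_bp: int
    label: str = "GFP"


@dataclass
class Genome:
    species_label: str
    chromosomes: list[Chromosome] = field(default_factory=list)
    markers: list[MarkerLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise GenomeError("duplicate chromosome names")
        if sum(c.is_sex for c in self.chromosomes) > 1:
            raise GenomeError("more than one sex chromosome")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def sex_chromosome(self) -> Optional[Chromosome]:
        for c in self.chromosomes:
            if c.is_sex:
                return c
        return None

    def total_length(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)


def read_genome(
    path: str | Path,
    species_label: Optional[str] = None,
    sex_pattern: str = r"(^|_)X$",
) -> Genome:
    """Read a genome from FASTA.

    The X chromosome is identified by matching ``sex_pattern`` against the
    record id (configurable; the default matches names ending in ``X``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pat = re.compile(sex_pattern)
    chroms: list[Chromosome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeError(f"empty FASTA record: {rec.id!r}")
        chroms.append(
            Chromosome(
                name=rec.id,
                length_bp=len(seq),
                sequence=seq,
                is_sex=bool(pat.search(rec.id)),
            )
        )
    if not chroms:
        raise GenomeError(f"no FASTA records in {path}")
    return Genome(species_label=species_label or path.stem, chromosomes=chroms)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise GenomeError(f"chromosome {c.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear physical<->genetic map, one anchor track per chromosome.

    Anchors are (physical_bp, genetic_cM) pairs; the first must be (0, 0),
    both coordinates strictly increasing, and the last physical anchor equal
    to the chromosome length.  No Haldane/Kosambi map function is applied:
    crossovers are simulated directly in genetic coordinates, making map
    functions unnecessary.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @staticmethod
    def from_anchors(spec: dict[str, Iterable[tuple[float, float]]]) -> "GeneticMap":
        m = GeneticMap()
        for chrom, pts in spec.items():
            pts = sorted(pts)
            phys = np.array([p for p, _ in pts], dtype=float)
            gen = np.array([g for _, g in pts], dtype=float)
            if phys[0] != 0 or gen[0] != 0:
                raise GenomeError(f"{chrom}: first map anchor must be (0, 0)")
            if np.any(np.diff(phys) <= 0) or np.any(np.diff(gen) <= 0):
                raise GenomeError(f"{chrom}: map anchors must be strictly increasing")
            m.anchors[chrom] = (phys, gen)
        return m

    @staticmethod
    def uniform(genome_or_lengths, cm_per_chrom: float = 50.0) -> "GeneticMap":
        """A flat map: ``cm_per_chrom`` spread evenly over each chromosome."""
        lengths = _as_lengths(genome_or_lengths)
        return GeneticMap.from_anchors(
            {n: [(0, 0.0), (L, cm_per_chrom)] for n, L in lengths.items()}
        )

    @staticmethod
    def arm_weighted(
        genome_or_lengths,
        arm_cm: float = 20.0,
        center_cm: float = 10.0,
        arm_fraction: float = 0.25,
    ) -> "GeneticMap":
        """Arm-biased map: each physical arm (outer ``arm_fraction`` of the
        chromosome) carries ``arm_cm``, the physical center ``center_cm``.

        This mirrors the elevated recombination rate of Caenorhabditis
        chromosome arms relative to their centers.
        """
        lengths = _as_lengths(genome_or_lengths)
        spec = {}
        for n, L in lengths.items():
            a = arm_fraction * L
            spec[n] = [
                (0, 0.0),
                (a, arm_cm),
                (L - a, arm_cm + center_cm),
                (L, 2 * arm_cm + center_cm),
            ]
        return GeneticMap.from_anchors(spec)

    def chrom_length_bp(self, chrom: str) -> int:
        return int(self.anchors[chrom][0][-1])

    def map_length_cm(self, chrom: str) -> float:
        return float(self.anchors[chrom][1][-1])

    def physical_to_genetic(self, chrom: str, pos_bp: float) -> float:
        phys, gen = self._track(chrom)
        if pos_bp < 0 or pos_bp > phys[-1]:
            raise GenomeError(f"{chrom}: position {pos_bp} outside [0, {phys[-1]}]")
        return float(np.interp(pos_bp, phys, gen))

    def genetic_to_physical(self, chrom: str, pos_cm: float) -> float:
        phys, gen = self._track(chrom)
        if pos_cm < 0 or pos_cm > gen[-1]:
            raise GenomeError(f"{chrom}: {pos_cm} cM outside [0, {gen[-1]}]")
        return float(np.interp(pos_cm, gen, phys))

    def _track(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.anchors[chrom]
        except KeyError:
            raise GenomeError(f"no genetic map for chromosome {chrom!r}") from None

    def validate_against(self, genome: Genome) -> None:
        for c in genome.chromosomes:
            if c.is_contaminant:
                continue
            if c.name not in self.anchors:
                raise GenomeError(f"no map track for {c.name!r}")
            if self.chrom_length_bp(c.name) != c.length_bp:
                raise GenomeError(
                    f"{c.name}: map end {self.chrom_length_bp(c.name)} != "
                    f"chromosome length {c.length_bp}"
                )


def _as_lengths(genome_or_lengths) -> dict[str, int]:
    if isinstance(genome_or_lengths, Genome):
        return {
            c.name: c.length_bp
            for c in genome_or_lengths.chromosomes
            if not c.is_contaminant
        }
    return dict(genome_or_lengths)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a tab-separated map with columns chrom, physical_bp, genetic_cM."""
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "physical_bp", "genetic_cM"}
    if not expected.issubset(df.columns):
        raise GenomeError(f"genetic map must have columns {sorted(expected)}")
    spec = {
        str(chrom): list(zip(sub["physical_bp"], sub["genetic_cM"]))
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return GeneticMap.from_anchors(spec)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom, (phys, gen) in gmap.anchors.items():
        for p, g in zip(phys, gen):
            rows.append({"chrom": chrom, "physical_bp": int(p), "genetic_cM": g})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    kind: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomeError(
                f"feature {self.kind} {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    features: list[Feature] = field(default_factory=list)

    def on(self, chrom: str, kind: Optional[str] = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.chrom == chrom and (kind is None or f.kind == kind)
        ]

    def kinds(self) -> set[str]:
        return {f.kind for f in self.features}

    def add(self, feature: Feature) -> None:
        self.features.append(feature)

    def validate_against(self, genome: Genome) -> None:
        for f in self.features:
            if f.chrom not in genome:
                raise GenomeError(f"feature on unknown chromosome {f.chrom!r}")
            if f.end > genome[f.chrom].length_bp:
                raise GenomeError(
                    f"feature {f.chrom}:{f.start}-{f.end} exceeds chromosome end"
                )


def intergenic_complement(
    annotation: AnnotationSet, genome: Genome, gene_kinds: tuple[str, ...] = ("exon", "intron")
) -> list[Feature]:
    """Derive intergenic intervals as the complement of gene spans.

    Together with merged gene spans the result partitions each chromosome:
    no gaps, no overlaps.
    """
    out: list[Feature] = []
    for c in genome.chromosomes:
        spans = sorted(
            (f.start, f.end) for f in annotation.on(c.name) if f.kind in gene_kinds
        )
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        for s, e in merged:
            if s > cursor:
                out.append(Feature(c.name, cursor, s, "intergenic"))
            cursor = max(cursor, e)
        if cursor < c.length_bp:
            out.append(Feature(c.name, cursor, c.length_bp, "intergenic"))
    return out


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read features from GFF3 or BED, normalising to 0-based half-open.

    GFF3 is 1-based closed (start shifted down by one on read); BED is
    already half-open.  The feature kind is taken from the GFF3 ``type``
    column or the BED name column.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed"}:
        return _read_bed(path)
    return _read_gff3(path)


def _read_bed(path: Path) -> AnnotationSet:
    ann = AnnotationSet()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"{path}:{i}: BED line with <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            kind = parts[3] if len(parts) > 3 else "region"
            strand = parts[5] if len(parts) > 5 else "."
            ann.add(Feature(chrom, start, end, kind, strand))
    return ann


def _read_gff3(path: Path) -> AnnotationSet:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", id_spec=None,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as err:  # gffutils raises assorted parse errors
        raise GenomeError(f"cannot parse GFF3 {path}: {err}") from err
    ann = AnnotationSet()
    for f in db.all_features():
        # GFF3 is 1-based closed -> internal half-open
        ann.add(Feature(f.seqid, f.start - 1, f.end, f.featuretype, f.strand or "."))
    return ann


def write_annotation(ann: AnnotationSet, path: str | Path, fmt: str = "gff3") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for f in ann.features:
                fh.write(
                    f"{f.chrom}\tintrogmap\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t.\n"
                )
        elif fmt == "bed":
            for f in ann.features:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.kind}\t0\t{f.strand}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


def format_mb(pos_bp: float) -> str:
    """Megabases with one decimal, the convention of the summary reports."""
    return f"{pos_bp / 1e6:.1f}"
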