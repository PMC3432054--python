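"""Synthetic sister-genome pair generator.

Produces a divergence-structured pair of genomes (a focal *donor* and a
*recipient* derived from it) plus exon/intron/intergenic/repeat annotation,
so that primer design, in-silico PCR and introgression simulation can all be
exercised end to end without any external assemblies.

The contrast the downstream methods need is conservation structure, not
phylogenetic realism: exons and repeat tracts stay nearly identical between
the two genomes while introns and intergenic sequence diverge heavily
(substitutions plus short indels).  Two observed failure modes of real
species pairs can be injected on top: contaminant contigs in the recipient
assembly, and shared haplotype tracts in which the recipient carries the
donor's sequence verbatim (wild-introgression mimicry).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genome import (
    AnnotationSet,
    Chromosome,
    Feature,
    GeneticMap,
    Genome,
    GenomeError,
    MarkerLocus,
    intergenic_complement,
    write_annotation,
    write_genetic_map,
    write_genome,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")


@dataclass
class DivergenceConfig:
    """Parameters of the sister-pair generator.

    Notes on the divergence defaults: intergenic/intronic sequence between
    genuinely distinct sister species is largely unalignable, and the whole
    primer-design pipeline hinges on that (a local-alignment screen with a
    raw-score cutoff of 50 rejects any region retaining long stretches of
    homology).  The non-exonic substitution rate therefore defaults to 0.45
    with a 5% indel initiation rate, which drives the per-base local
    alignment score drift negative (2*0.55 - 3*0.45 < 0) so that most
    non-exonic regions pass the screen while borderline ones are rejected
    and re-selected nearby, as happens with real panels.  Exons stay at 2%
    divergence, preserving the coding-conservation contrast.
    """

    seed: int = 0
    n_autosomes: int = 5
    chrom_length_bp: int = 15_000
    exon_fraction: float = 0.20
    repeat_fraction: float = 0.05
    substitution_rate_exonic: float = 0.02
    substitution_rate_nonexonic: float = 0.45
    indel_rate_nonexonic: float = 0.05
    mean_indel_bp: float = 4.0
    contaminant_contig_count: int = 0
    shared_haplotype_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "exon_fraction",
            "repeat_fraction",
            "substitution_rate_exonic",
            "substitution_rate_nonexonic",
            "indel_rate_nonexonic",
            "shared_haplotype_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.substitution_rate_exonic > self.substitution_rate_nonexonic:
            raise ValueError(
                "coding conservation requires substitution_rate_exonic <= "
                "substitution_rate_nonexonic"
            )
        if self.exon_fraction + self.repeat_fraction > 0.9:
            raise ValueError("exon_fraction + repeat_fraction exceed capacity")
        if self.n_autosomes < 1 or self.chrom_length_bp < 2000:
            raise ValueError("need >=1 autosome and chromosomes of >=2 kb")

    def chrom_names(self) -> list[str]:
        if self.n_autosomes <= len(_ROMAN):
            auto = list(_ROMAN[: self.n_autosomes])
        else:
            auto = [f"A{i + 1}" for i in range(self.n_autosomes)]
        return auto + ["X"]


@dataclass
class HomologyMap:
    """Piecewise donor->recipient coordinate correspondence.

    Anchored at every indel boundary; between anchors the offset is
    constant, so homologous positions are recovered exactly.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def donor_to_recipient(self, chrom: str, pos: int) -> int:
        d, r = self.anchors[chrom]
        i = int(np.searchsorted(d, pos, side="right")) - 1
        return int(r[i] + (pos - d[i]))


@dataclass
class SisterPair:
    donor: Genome
    recipient: Genome
    annotation: AnnotationSet
    homology: HomologyMap
    config: DivergenceConfig
    shared_tracts: list[Feature] = field(default_factory=list)


def _chrom_rng(seed: int, name: str, salt: int = 0) -> np.random.Generator:
    # keyed by chromosome name so processing order cannot change the draws
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()), salt])


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _from_str(s: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _layout_chromosome(
    rng: np.random.Generator, name: str, L: int, exon_fraction: float, repeat_fraction: float
) -> list[Feature]:
    """Lay out genes (exons separated by introns) and repeat tracts."""
    feats: list[Feature] = []
    exon_target = exon_fraction * L
    exon_bp = 0
    pos = 0
    while pos < L - 600 and exon_bp < exon_target:
        pos += int(rng.integers(300, 1200))  # intergenic gap before the gene
        n_ex = int(rng.integers(2, 6))
        for k in range(n_ex):
            elen = int(rng.integers(120, 300))
            if pos + elen > L:
                break
            feats.append(Feature(name, pos, pos + elen, "exon"))
            exon_bp += elen
            pos += elen
            if k < n_ex - 1:
                ilen = int(rng.integers(200, 600))
                if pos + ilen > L - 150:
                    break
                feats.append(Feature(name, pos, pos + ilen, "intron"))
                pos += ilen
    # explicit intergenic complement
    gene_spans = sorted((f.start, f.end) for f in feats)
    cursor = 0
    inter: list[tuple[int, int]] = []
    for s, e in gene_spans:
        if s > cursor:
            inter.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < L:
        inter.append((cursor, L))
    feats.extend(Feature(name, s, e, "intergenic") for s, e in inter)
    # tandem-repeat tracts inside intergenic intervals (may overlap nothing else)
    rep_target = repeat_fraction * L
    rep_bp = 0
    candidates = [iv for iv in inter if iv[1] - iv[0] >= 500]
    attempts = 0
    placed: list[tuple[int, int]] = []
    while rep_bp < rep_target and candidates and attempts < 200:
        attempts += 1
        s, e = candidates[int(rng.integers(len(candidates)))]
        tlen = int(rng.integers(150, 301))
        if e - s - 100 <= tlen:
            continue
        start = int(rng.integers(s + 50, e - 50 - tlen))
        if any(start < pe and start + tlen > ps for ps, pe in placed):
            continue
        placed.append((start, start + tlen))
        feats.append(Feature(name, start, start + tlen, "repeat"))
        rep_bp += tlen
    return feats


def _mutate_chromosome(
    rng: np.random.Generator,
    donor: np.ndarray,
    low_div_mask: np.ndarray,
    cfg: DivergenceConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply class-dependent substitutions and non-conserved indels.

    Returns (recipient array, donor anchor positions, recipient anchors).
    """
    L = donor.size
    rate = np.where(
        low_div_mask, cfg.substitution_rate_exonic, cfg.substitution_rate_nonexonic
    )
    sub = rng.random(L) < rate
    shift = rng.integers(1, 4, size=L).astype(np.uint8)
    base = donor.copy()
    base[sub] = (base[sub] + shift[sub]) % 4

    eligible = ~low_div_mask
    ind = np.flatnonzero((rng.random(L) < cfg.indel_rate_nonexonic) & eligible)
    is_ins = rng.random(ind.size) < 0.5
    lens = rng.geometric(1.0 / cfg.mean_indel_bp, size=ind.size)
    protected_starts = np.flatnonzero(np.diff(low_div_mask.astype(np.int8)) == 1) + 1

    pieces: list[np.ndarray] = []
    anchors_d = [0]
    anchors_r = [0]
    cur_d = 0
    cur_r = 0
    for p, ins, l in zip(ind.tolist(), is_ins.tolist(), lens.tolist()):
        if p < cur_d:
            continue  # swallowed by a previous deletion
        pieces.append(base[cur_d:p])
        cur_r += p - cur_d
        cur_d = p
        if ins:
            pieces.append(rng.integers(0, 4, size=l).astype(np.uint8))
            cur_r += l
        else:
            # deletions never run into a conserved (exon/repeat) block
            j = int(np.searchsorted(protected_starts, p, side="left"))
            stop = int(protected_starts[j]) if j < protected_starts.size else L
            cur_d = min(p + l, stop, L)
        anchors_d.append(cur_d)
        anchors_r.append(cur_r)
    pieces.append(base[cur_d:])
    recip = np.concatenate(pieces) if pieces else base
    return recip, np.array(anchors_d), np.array(anchors_r)


def generate_sister_pair(config: DivergenceConfig) -> SisterPair:
    """Generate the donor genome, its diverged recipient, and annotation.

    The recipient is derived from the donor directly (no common-ancestor
    simulation): exons and repeat tracts mutate at the low (exonic) rate and
    never receive indels, everything else at the high rate with geometric
    indels.  Identical seeds give byte-identical output.
    """
    cfg = config
    donor_chroms: list[Chromosome] = []
    recip_chroms: list[Chromosome] = []
    ann = AnnotationSet()
    hom = HomologyMap()
    for name in cfg.chrom_names():
        rng = _chrom_rng(cfg.seed, name)
        L = cfg.chrom_length_bp
        feats = _layout_chromosome(rng, name, L, cfg.exon_fraction, cfg.repeat_fraction)
        d = rng.integers(0, 4, size=L).astype(np.uint8)
        low_div = np.zeros(L, dtype=bool)
        for f in feats:
            if f.kind == "repeat":
                motif = rng.integers(0, 4, size=6).astype(np.uint8)
                tile = np.tile(motif, f.length // 6 + 1)[: f.length]
                d[f.start : f.end] = tile
            if f.kind in ("exon", "repeat"):
                low_div[f.start : f.end] = True
        r, ad, ar = _mutate_chromosome(rng, d, low_div, cfg)
        is_x = name == "X"
        donor_chroms.append(Chromosome(name, L, _to_str(d), is_sex=is_x))
        recip_chroms.append(Chromosome(name, r.size, _to_str(r), is_sex=is_x))
        hom.anchors[name] = (ad, ar)
        for f in feats:
            ann.add(f)
    # contaminant contigs: unrelated random backbone carrying donor-like exons
    for k in range(cfg.contaminant_contig_count):
        cname = f"contam_{k + 1}"
        rng = _chrom_rng(cfg.seed, cname, salt=7)
        L = max(2000, cfg.chrom_length_bp // 2)
        seq = rng.integers(0, 4, size=L).astype(np.uint8)
        donor_exons = [f for f in ann.features if f.kind == "exon"]
        for _ in range(min(5, len(donor_exons))):
            f = donor_exons[int(rng.integers(len(donor_exons)))]
            src = _from_str(donor_chroms[[c.name for c in donor_chroms].index(f.chrom)].sequence)
            frag = src[f.start : f.end]
            pos = int(rng.integers(0, L - frag.size))
            seq[pos : pos + frag.size] = frag
        recip_chroms.append(
            Chromosome(cname, L, _to_str(seq), is_sex=False, is_contaminant=True)
        )
    donor = Genome("donor", donor_chroms)
    recipient = Genome("recipient", recip_chroms)
    pair = SisterPair(donor, recipient, ann, hom, cfg)
    if cfg.shared_haplotype_fraction > 0:
        recipient, tracts = inject_shared_haplotypes(
            recipient, donor, cfg.shared_haplotype_fraction, cfg.seed
        )
        pair.recipient = recipient
        pair.shared_tracts = tracts
    return pair


def inject_shared_haplotypes(
    recipient: Genome,
    donor: Genome,
    fraction: float,
    seed: int,
    tract_mean_bp: int = 1500,
) -> tuple[Genome, list[Feature]]:
    """Copy contiguous donor tracts verbatim into the recipient.

    Emulates a wild recipient isolate that shares haplotypes with the donor
    species through natural interbreeding: inside a tract the recipient is
    sequence-identical to the donor, so donor-specific primers located there
    amplify both genomes.  Returns the modified genome and the ground-truth
    tract coordinates (donor coordinates; tract content is the donor
    sequence at those coordinates).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    new_chroms: list[Chromosome] = []
    tracts: list[Feature] = []
    for rc in recipient.chromosomes:
        if rc.is_contaminant or fraction == 0.0 or rc.name not in donor:
            new_chroms.append(rc)
            continue
        dc = donor[rc.name]
        if fraction >= 1.0:
            new_chroms.append(
                Chromosome(rc.name, dc.length_bp, dc.sequence, rc.is_sex)
            )
            tracts.append(Feature(rc.name, 0, dc.length_bp, "shared_haplotype"))
            continue
        rng = _chrom_rng(seed, rc.name, salt=11)
        L = min(dc.length_bp, rc.length_bp)
        target = int(round(fraction * L))
        n = max(1, int(round(target / tract_mean_bp)))
        tlen = max(1, target // n)
        starts: list[int] = []
        attempts = 0
        while len(starts) < n and attempts < 500:
            attempts += 1
            s = int(rng.integers(0, L - tlen))
            if all(abs(s - t) >= tlen for t in starts):
                starts.append(s)
        seq = list(rc.sequence)
        dseq = dc.sequence
        for s in sorted(starts):
            seq[s : s + tlen] = dseq[s : s + tlen]
            tracts.append(Feature(rc.name, s, s + tlen, "shared_haplotype"))
        new_chroms.append(
            Chromosome(rc.name, rc.length_bp, "".join(seq), rc.is_sex)
        )
    return Genome(recipient.species_label, new_chroms, list(recipient.markers)), tracts


def insert_marker(
    genome: Genome, locus: MarkerLocus, cassette_length_bp: int = 0
) -> Genome:
    """Record a dominant visible marker at a genomic locus.

    The cassette is modelled as a zero-footprint tag: carriers are detected
    by fluorescence, not by sequence, so the insertion does not rewrite the
    chromosome (``cassette_length_bp`` is metadata only).  Downstream, an
    individual carries the marker iff a donor-ancestry segment covers the
    locus.
    """
    if locus.chrom not in genome:
        raise GenomeError(f"marker chromosome {locus.chrom!r} not in genome")
    chrom = genome[locus.chrom]
    if chrom.is_contaminant:
        raise GenomeError(f"cannot place a marker on contaminant contig {locus.chrom!r}")
    if not 0 <= locus.position_bp < chrom.length_bp:
        raise GenomeError(
            f"marker position {locus.position_bp} outside {locus.chrom} "
            f"[0, {chrom.length_bp})"
        )
    genome.markers.append(locus)
    return genome


def write_fixture(pair: SisterPair, outdir: str | Path, gmap: Optional[GeneticMap] = None) -> dict:
    """Write the fixture to disk: FASTA x2, GFF3, BED tracts, map TSV, JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "donor": outdir / "donor.fa",
        "recipient": outdir / "recipient.fa",
        "annotation": outdir / "annotation.gff3",
        "config": outdir / "config.json",
    }
    write_genome(pair.donor, paths["donor"])
    write_genome(pair.recipient, paths["recipient"])
    write_annotation(pair.annotation, paths["annotation"])
    if pair.shared_tracts:
        paths["shared_tracts"] = outdir / "shared_tracts.bed"
        write_annotation(AnnotationSet(pair.shared_tracts), paths["shared_tracts"], fmt="bed")
    if gmap is None:
        gmap = GeneticMap.arm_weighted(pair.donor)
    paths["genetic_map"] = outdir / "genetic_map.tsv"
    write_genetic_map(gmap, paths["genetic_map"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(pair.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
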