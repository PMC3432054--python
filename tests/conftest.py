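import numpy as np
import pytest
from hypothesis import settings

import introgmap as im

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sister() -> im.SisterPair:
    """Small sister-genome pair: two autosomes plus X, 12 kb each."""
    cfg = im.DivergenceConfig(seed=FIXTURE_SEED, n_autosomes=2, chrom_length_bp=12_000)
    return im.generate_sister_pair(cfg)


@pytest.fixture(scope="session")
def small_spec() -> im.PanelSpec:
    return im.PanelSpec(
        primers_per_chromosome=6,
        product_size_range=(120, 400),
        candidate_region_length_bp=420,
        reselection_step_bp=300,
    )


@pytest.fixture(scope="session")
def designed(sister, small_spec) -> im.PanelDesign:
    return im.design_panel(sister.donor, sister.recipient, sister.annotation, spec=small_spec)


@pytest.fixture(scope="session")
def fixture_map(sister) -> im.GeneticMap:
    return im.GeneticMap.arm_weighted(sister.donor)


def demo_karyotype(n_autosomes: int = 5, length: int = 15_000_000):
    """Coordinate-only 15 Mb karyotype (autosomes + X) with its arm-weighted
    50 cM map: arms carry 20 cM each over the outer quarters, the center 10 cM."""
    names = ["I", "II", "III", "IV", "V"][:n_autosomes] + ["X"]
    chroms = [im.Chromosome(n, length, is_sex=(n == "X")) for n in names]
    donor = im.Genome("donor", chroms)
    recipient = im.Genome(
        "recipient", [im.Chromosome(c.name, c.length_bp, is_sex=c.is_sex) for c in chroms]
    )
    gmap = im.GeneticMap.arm_weighted(donor)
    return donor, recipient, gmap


def coordinate_panel(chrom: str, length: int, n: int, product: int = 300):
    """Synthetic panel of n evenly spaced pairs on one chromosome
    (coordinate-mode genotyping only; sequences are placeholders)."""
    pairs = []
    for j in range(n):
        mid = int((j + 0.5) * length / n)
        left = max(0, mid - product // 2)
        third = length / 3
        arm = "left" if mid < third else ("middle" if mid < 2 * third else "right")
        pairs.append(
            im.PrimerPair(
                id=f"{chrom}-{j + 1:02d}",
                chrom=chrom,
                left_seq="ACGTACGTACGTACGTACGTAC",
                right_seq="GTCAGTCAGTCAGTCAGTCAGT",
                left_start=left,
                right_end=left + product,
                product_size_bp=product,
                arm_label=arm,
                status="retained",
            )
        )
    return pairs


def pure_individual(genome: im.Genome, marker: im.MarkerLocus, origin: str) -> im.Individual:
    """Individual homozygous for a single ancestry, for PCR truth tables."""
    haps = {
        c.name: [
            im.Haplotype.uniform(c.name, c.length_bp, origin),
            im.Haplotype.uniform(c.name, c.length_bp, origin),
        ]
        for c in genome.chromosomes
        if not c.is_contaminant
    }
    x = genome.sex_chromosome
    return im.Individual(
        sex="female", haplotypes=haps, marker=marker, generation=0,
        x_chrom=x.name if x else None,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
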