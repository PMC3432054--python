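# Methods

`introgmap` models a mapping workflow for dominant, visible loci in a
nematode sister-species pair: a transgene-carrying donor genome is crossed
into the recipient species' background by repeated marker-selected
backcrossing, and the retained donor fragment is located and sized by
single-worm PCR with donor-specific primer pairs. This note records the
models, the parameter choices that matter, and the design decisions taken
where the design was genuinely open.

## Genomes, maps, coordinates

Internally every coordinate is 0-based half-open; GFF3 is converted at the
I/O boundary and reports print 1-based megabases with one decimal. The
genetic map is piecewise linear between anchor points `(physical_bp,
genetic_cM)`; no Haldane/Kosambi map function is applied because crossovers
are simulated directly in genetic coordinates, where recombination
fractions are exact by construction. The demonstration karyotype is five
15 Mb autosomes plus an X, each with an arm-weighted 50 cM map (outer
quarters carry 20 cM each, the center 10 cM), reflecting the elevated arm
recombination of *Caenorhabditis* chromosomes.

## Synthetic sister genomes

The generator derives the recipient genome from the donor directly rather
than simulating a common ancestor: downstream methods need only the
conservation contrast, not phylogenetic realism. Exons and repeat tracts
mutate at the low rate (default 2% substitutions, no indels, keeping exon
annotation valid on both genomes); introns and intergenic sequence mutate
heavily and accumulate geometric indels. Repeats are tandem copies of a
short motif placed in intergenic sequence and kept near-identical between
the genomes, so the repeat-exclusion filter in primer design has real
consequences.

Two defaults deserve explanation:

* **Non-exonic divergence 45% (+5% indel initiation, mean 4 bp).** The
  species-specificity screen rejects candidate regions whose best local
  alignment against the recipient scores above 50 (match +2, mismatch −3).
  A long homolog at 85% identity scores ≈ +1.25 per base — hundreds for any
  400–500 bp region — so at mild divergence *no* region can pass and panel
  design is infeasible. Genuinely distinct sister species have largely
  unalignable intergenic sequence; 45% substitution puts the per-base score
  drift below zero (2·0.55 − 3·0.45 < 0), so most regions pass while
  borderline ones are rejected and re-selected nearby, reproducing the
  iterative selection a real panel goes through.
* **Chromosome length 15 kb (sequence fixtures).** The 3′-specificity
  filter discards a primer whose 3′-terminal sequence matches the recipient
  exactly for more than 8 bases, searched genome-wide on both strands. The
  expected longest random 9-mer hit grows with log₄(genome size): at Mb
  scale every primer fails by chance alone, at ~100 kb of total recipient
  sequence the filter is a real but passable constraint. Sequence-level
  stages therefore run on compact genomes, while coordinate-level stages
  (introgression, genotyping, interval reports) use the full 15 Mb
  karyotype, where only lengths and maps matter.

Failure modes observed with real assemblies can be injected: contaminant
contigs (unrelated backbone carrying donor-like exons, emitted as extra
recipient records) and shared haplotype tracts — contiguous stretches where
the recipient carries the donor sequence verbatim, emulating a wild
recipient isolate with natural introgression from the donor species.
Tract coordinates are returned as ground truth: a primer pair amplifies the
modified recipient exactly when both its binding sites lie inside tracts,
and with tract fraction *f* the fraction of a previously specific panel
that cross-amplifies converges to ≈ *f*.

The marker cassette is modelled as a zero-footprint tag: carriers are
recognised by fluorescence, not sequence, so insertion records a locus
without rewriting coordinates.

## Primer panel design

Per chromosome, `primers_per_chromosome` (default 15) target positions are
laid out with arm-biased density (weights 0.4/0.2/0.4 over physical
thirds). Around each target the pipeline iterates: select the nearest
window (default 500 bp) lying wholly in intron/intergenic sequence and
overlapping no repeat; reject it if its Smith–Waterman raw score against
the recipient exceeds 50 (a score of exactly 50 is retained); pick the best
primer pair; reject the pair if either primer's longest exact 3′-anchored
recipient match exceeds 8 bp; on any failure re-select a nearby window
(alternating outward, default 50 steps) and log the cause.

Alignment scores are exact Smith–Waterman optima (Biopython's C aligner)
under match +2, mismatch −3, gap of length *k* costing 5 + 2*k*, maximised
over both strands — so the score-50 cutoff has a sharp meaning: more than
25 contiguous identical bases trip it on their own. Raw score (not bit
score) is used. The test suite re-derives scores with an independent
pure-Python dynamic program.

Primer constraints: length 18–27 nt, nearest-neighbor Tm 55–62 °C
(consistent with a 55 °C annealing protocol), GC 35–65%, no homopolymer
run over 4, product size within a configurable range. The picker scans
candidates inward from the window ends and breaks ties by smallest pair Tm
difference, then leftmost coordinate — fully deterministic, and invariant
to chromosome processing order because chromosomes are independent.

A finished panel is validated by in-silico amplification of every pair
against both genomes; pairs producing a recipient product are discarded
(`retained = candidates − cross-amplifying`). Retained pairs amplify the
donor and only the donor, by construction.

## In-silico PCR

Two modes, deliberately centralised so they can only diverge in one place:

* **Coordinate mode** (for simulated individuals): a pair is positive iff
  one haplotype carries a single donor-ancestry segment covering both
  primer intervals. Heterozygous suffices; trans configurations and
  junction-split templates do not amplify, because a physical template must
  be contiguous.
* **Sequence mode** (for genomes/templates): a binding site is an exact
  match of the primer's 15 nt 3′ core with at most 2 mismatches over the
  rest; a facing site pair within 2 kb (default) amplifies, on either
  strand. This is a deliberate simplification of hybridisation kinetics.

The two modes agree on individuals rendered to sequence (donor segments
contribute donor sequence; recipient segments the homologous recipient
sequence located through the generator's indel-aware coordinate map).

## Introgression simulation

Haplotypes are ordered donor/recipient ancestry segments in donor physical
coordinates. The F1 is female (hybrid F1 males are inviable/sterile and
simply not modelled), heterozygous genome-wide, generation 1. Each
backcross round crosses the carrier to a pure recipient and selects the
first marker-positive offspring of the required sex from a brood (default
20; animal counts of the wet protocol affect only per-cross success
probability, not segment genetics). Autosomal schemes accept any sex;
X-linked schemes with the large-X effect select females only, without it
the crossing direction alternates by generation parity. Sex follows X
transmission (XX female, X0 male); the male X is transmitted without
recombination. `generations` counts backcross rounds after the F1, which
equals the number of marker-selected informative meioses *t*.

Crossover models:

* `obligate_single` (default): one crossover per bivalent at a uniform
  genetic position; the transmitted chromatid is recombinant with
  probability 1/2, otherwise a parental haplotype chosen equiprobably.
  This is the near-complete-interference regime of *Caenorhabditis*
  meiosis; the whole-chromosome recombinant fraction is 1/2 regardless of
  map length.
* `poisson`: crossover count on the transmitted gamete ~ Poisson(map
  length in Morgans), positions i.i.d. uniform in genetic coordinates,
  starting strand equiprobable. Gamete-level rates are used because the
  marker-flank retention then has the closed form
  E[L] = (1 − e^(−t·d))/t Morgans for a flank of d Morgans after t
  marker-selected meioses — the analytically checkable alternative
  (drawing Poisson(L) on the bivalent and thinning by strand choice would
  halve the rate and break both the 50 cM → 0.5 crossovers-per-gamete
  expectation and the closed form).

Randomness comes from independent per-chromosome streams keyed by
`(seed, chromosome name)`, so chromosome reordering cannot change any
chromosome's draws and runs are bit-reproducible under a fixed seed.

Under the default model and map, eight backcross generations with a
mid-arm marker retain a marker-linked donor segment whose model mean is
≈ 4.8–4.9 Mb (the survival function of one flank is (1−g)^t in Morgans,
integrated against the arm-weighted cM→Mb density; the center's 0.75
Mb/cM expansion dominates the physical size). Because the per-replicate
spread is large (SD ≈ 4 Mb), simulation-based summaries here use 3000
replicates, putting the Monte-Carlo standard error near 0.07 Mb.

## Genotyping and inference

The hierarchical strategy runs one pair per arm (left/middle/right) on
each autosome — 15 reactions — then the remaining pairs of the implicated
chromosome: 15 + (n − 3) = 27 reactions for a 15-pair chromosome, within
the 30-reaction budget; a known X linkage costs only the X panel (≤ 13).
Arm representatives are the median pair of each arm group: a
representative near the arm's center catches mid-arm segments that an
edge pair would systematically miss. Positives on several chromosomes are
reported as a flag, not an error — they indicate assembly anomalies or
co-segregating modifiers worth inspecting.

The marker interval is reported as the span of the outermost positive
primers (`size_bp`), with the nearest flanking negative primers (or
chromosome ends) as the certain outer bracket. Maximal runs of positives
become separate intervals, so a single negative between positives splits a
discontinuous introgression into two reported segments. Denser panels can
only shrink or preserve the outer bracket. Note that the *inner* span is
guaranteed to contain the marker only when in-segment primers flank it on
both sides; two in-segment primers on the same side cannot contain it.

Two-point linkage from F2 segregation: with a repulsion-phase F1, the
marker-positive fraction among mutant-phenotype F2 is 2r − r², inverted by
r̂ = 1 − √(n_neg / n_total), clipped to [0, 0.5].

## What the synthetic fixtures do and do not show

Passing tests demonstrate internal consistency of design, simulation,
genotyping and inference under the generator's idealised divergence
structure: uniform base composition, block-uniform mutation rates, exact
repeat sharing, no sequencing error, assemblies with known homology. They
do not certify performance on real assemblies, where conservation is
patchy, repeats are divergent and annotation is imperfect; genome-scale
outcomes (real panel composition, ~1.1 Mb mean spacing, strain-specific
amplification in wild isolates) require real genomes and are covered here
only qualitatively (spacing arithmetic, shared-haplotype injection).

## Degenerate inputs and tie-breaks

Zero-divergence pairs are panel-infeasible (every region fails the
screen) and reported as such. A chromosome yielding fewer than three
retained pairs aborts design. Empty recipients pass the 3′ filter
trivially. Chromosomes with fewer than two retained pairs are omitted
from spacing statistics with a warning. Crossovers falling exactly on a
chromosome boundary are discarded (no recombination). All tie-breaks
(primer choice, region choice) resolve to the leftmost alternative.
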