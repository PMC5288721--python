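"""Synthetic paleotetraploid genomes with known ground truth.

The generator emulates the evolutionary scenario the rest of the pipeline is
built to detect: an ancestral diploid gene order is duplicated wholesale by a
single whole-genome duplication (WGD); each duplicated gene copy is then
independently lost with a fixed fractionation probability; segmental
inversions and translocations shuffle the duplicated chromosomes; and every
surviving coding sequence diverges along its branch under a two-parameter
(Kimura-type) codon-site substitution model with transition/transversion
ratio kappa and a nonsynonymous acceptance factor omega that thins
amino-acid-changing mutations. An outgroup genome splits from the ancestor
before the WGD, so each outgroup gene has up to two surviving homeologs in
the focal genome.

Branch lengths are expressed in expected substitutions per fourfold-
degenerate (4D) site per lineage: proposals arrive at per-site rate
(kappa+2)*beta and every proposal at a 4D third position is accepted, so the
scaling beta*T = L/(kappa+2) makes the expected number of accepted
substitutions at a 4D site equal L. Under this model the expected *corrected*
4DTv of a pair equals 2*d/(kappa+2) where d is the pair's total divergence;
with the default kappa=2 that is simply the per-lineage branch length.

Default parameters are chosen to emulate the rubber-tree system: kappa=2,
WGD branch 0.073 and speciation branch 0.14 substitutions per 4D site per
lineage (placing the self- and ortholog-comparison 4DTv peaks at 0.073 and
0.14), and per-copy loss probability 0.285, for which the expected share of
outgroup genes retaining both homeologs, (1-p)/(1+p), is 55.6%.

Every operation is deterministic given (params, seed); a TruthTable records
the surviving paralog/ortholog pairs, their expected and realized 4D
divergences, and per-ancestral-gene loss flags for parameter-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io_formats import FormatError, GeneModel, GenomeAnnotation, MarkerRecord
from .molevol import FOURFOLD_PREFIXES, SENSE_CODONS, STOP_CODONS, _CODON_TABLE

__all__ = [
    "EvolutionParams",
    "PairTruth",
    "TruthTable",
    "MapTruth",
    "SimulatedDataset",
    "simulate_ancestor",
    "apply_wgd_and_diverge",
    "emit_outgroup",
    "emit_synthetic_map",
    "simulate_paleotetraploid",
    "expected_corrected_4dtv",
    "expected_two_copy_fraction",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the simulated duplication history.

    Branch lengths are expected substitutions per 4D site per lineage;
    ``loss_probability`` is the per-duplicate-copy fractionation probability;
    ``omega_sim`` is the acceptance probability of amino-acid-changing
    mutations (the simulated Ka/Ks pressure); segment sizes for inversions
    and translocations are drawn uniformly from 5-20 genes.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 400
    codon_length_min: int = 250
    codon_length_max: int = 350
    intergenic_min: int = 200
    intergenic_max: int = 1000
    wgd_branch_length: float = 0.073
    speciation_branch_length: float = 0.14
    kappa: float = 2.0
    loss_probability: float = 0.285
    omega_sim: float = 0.2
    inversion_count: int = 0
    translocation_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        if not (0 <= self.loss_probability < 1):
            raise ValueError("loss_probability must be in [0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.wgd_branch_length < 0 or self.speciation_branch_length < 0:
            raise ValueError("branch lengths must be >= 0")
        if not (3 <= self.codon_length_min <= self.codon_length_max):
            raise ValueError("codon lengths must satisfy 3 <= min <= max")
        if self.inversion_count < 0 or self.translocation_count < 0:
            raise ValueError("event counts must be >= 0")


@dataclass(frozen=True)
class PairTruth:
    """Expected and realized 4D-site divergence (total, both lineages)."""

    expected: float
    realized: float


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    paralog_pairs: dict[tuple[str, str], PairTruth] = field(default_factory=dict)
    ortholog_pairs: dict[tuple[str, str], PairTruth] = field(default_factory=dict)
    #: ancestral gene id -> (copy a survives, copy b survives)
    loss_flags: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    #: surviving focal gene id -> realized 4D divergence since the speciation split
    focal_realized: dict[str, float] = field(default_factory=dict)

    def surviving_focal_ids(self, ancestral_id: str) -> list[str]:
        a, b = self.loss_flags[ancestral_id]
        out = []
        if a:
            out.append(ancestral_id + "a")
        if b:
            out.append(ancestral_id + "b")
        return out


@dataclass
class MapTruth:
    """Ground truth of a synthetic genetic map / fragmented assembly."""

    #: scaffold id -> (linkage group, order index within LG, orientation)
    scaffolds: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    #: marker id -> (seq_id, 1-based chromosome position of flank start)
    markers: dict[str, tuple[str, int]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """Bundle returned by the end-to-end simulation driver."""

    params: EvolutionParams
    ancestor: GenomeAnnotation
    focal: GenomeAnnotation
    outgroup: GenomeAnnotation
    truth: TruthTable


# ---------------------------------------------------------------------------
# closed-form expectations used by recovery tests and reports
# ---------------------------------------------------------------------------


def expected_corrected_4dtv(total_divergence: float, kappa: float) -> float:
    """Expected corrected 4DTv of a pair at the given total 4D divergence.

    Under the two-parameter model the transversion component of the
    divergence is 2*d/(kappa+2), and the -1/2*ln(1-2v) correction recovers
    exactly that component.
    """
    return 2.0 * total_divergence / (kappa + 2.0)


def expected_two_copy_fraction(loss_probability: float) -> float:
    """Among outgroup genes with >=1 surviving homeolog, share with two.

    Copies are lost independently with probability p, so
    P(both survive | >=1 survives) = (1-p)^2 / (1-p^2) = (1-p)/(1+p).
    """
    p = loss_probability
    return (1.0 - p) / (1.0 + p)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _evolve_cds(
    cds: str, branch_length: float, kappa: float, omega: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Evolve one CDS along a branch; return (new CDS, realized divergence).

    Realized divergence counts accepted substitutions at third positions of
    codons whose two-base prefix is fourfold degenerate at mutation time,
    normalised by the number of 4D codons at branch start.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n4d_start = sum(1 for c in codons if c[:2] in FOURFOLD_PREFIXES)
    if branch_length <= 0:
        return cds, 0.0
    p_transition = kappa / (kappa + 2.0)
    counts = rng.poisson(3.0 * branch_length, len(codons))
    n4d_subs = 0
    for idx in np.nonzero(counts)[0]:
        codon = codons[idx]
        for _ in range(counts[idx]):
            site = int(rng.integers(3))
            base = codon[site]
            if rng.random() < p_transition:
                new_base = _TRANSITION[base]
            else:
                new_base = _TRANSVERSIONS[base][int(rng.integers(2))]
            mutant = codon[:site] + new_base + codon[site + 1 :]
            if mutant in STOP_CODONS:
                continue
            if _CODON_TABLE[mutant] != _CODON_TABLE[codon] and rng.random() >= omega:
                continue
            if site == 2 and codon[:2] in FOURFOLD_PREFIXES:
                n4d_subs += 1
            codon = mutant
        codons[int(idx)] = codon
    realized = n4d_subs / n4d_start if n4d_start else 0.0
    return "".join(codons), realized


def _evolve_all(
    cds_map: Mapping[str, str],
    branch_length: float,
    params: EvolutionParams,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, float]]:
    evolved: dict[str, str] = {}
    realized: dict[str, float] = {}
    for gid in sorted(cds_map):
        evolved[gid], realized[gid] = _evolve_cds(
            cds_map[gid], branch_length, params.kappa, params.omega_sim, rng
        )
    return evolved, realized


# ---------------------------------------------------------------------------
# genome layout helpers
# ---------------------------------------------------------------------------


def _layout_chromosome(
    seq_id: str,
    ordered: list[tuple[str, str, str]],
    params: EvolutionParams,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], str]:
    """Place (gene_id, cds, strand) triplets on a fresh chromosome sequence."""
    genes: list[GeneModel] = []
    pieces: list[str] = []
    cursor = 0  # bases laid down so far
    for gene_id, cds, strand in ordered:
        gap = int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
        pieces.append(
            "".join(rng.choice(("A", "C", "G", "T"), size=gap))
        )
        start = cursor + gap + 1
        end = start + len(cds) - 1
        pieces.append(cds if strand == "+" else _revcomp(cds))
        cursor = end
        genes.append(GeneModel(gene_id, seq_id, start, end, strand))
    tail = int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
    pieces.append("".join(rng.choice(("A", "C", "G", "T"), size=tail)))
    return genes, "".join(pieces)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_ancestor(
    params: EvolutionParams, rng: np.random.Generator | None = None
) -> GenomeAnnotation:
    """Generate the pre-WGD ancestral genome.

    ``n_chromosomes * genes_per_chromosome`` genes with random strands and
    non-overlapping coordinates; each CDS starts with ATG, contains no
    internal stop, and has a random length between the configured bounds.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes: list[GeneModel] = []
    cds: dict[str, str] = {}
    chromosomes: dict[str, str] = {}
    for c in range(1, params.n_chromosomes + 1):
        seq_id = f"chr{c}"
        ordered = []
        for i in range(params.genes_per_chromosome):
            gid = f"g{c:02d}{i:04d}"
            n_codons = int(
                rng.integers(params.codon_length_min, params.codon_length_max + 1)
            )
            cds[gid] = _random_cds(n_codons, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            ordered.append((gid, cds[gid], strand))
        placed, seq = _layout_chromosome(seq_id, ordered, params, rng)
        genes.extend(placed)
        chromosomes[seq_id] = seq
    return GenomeAnnotation.from_genes("ancestor", genes, cds, chromosomes)


def _pick_segment(
    n_genes: int, rng: np.random.Generator, lo: int = 5, hi: int = 20
) -> tuple[int, int]:
    size = int(rng.integers(lo, hi + 1))
    size = min(size, n_genes)
    start = int(rng.integers(0, n_genes - size + 1))
    return start, start + size


def apply_wgd_and_diverge(
    ancestor: GenomeAnnotation,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    pre_realized: Mapping[str, float] | None = None,
) -> tuple[GenomeAnnotation, TruthTable]:
    """Duplicate every chromosome, fractionate, rearrange and diverge.

    Each ancestral gene yields copies ``<id>a`` on ``<seq>a`` and ``<id>b``
    on ``<seq>b``; each copy is independently deleted with
    ``loss_probability``; surviving CDS evolve along a branch of
    ``wgd_branch_length``; the requested number of segmental inversions and
    translocations is then applied to the duplicated chromosomes, and
    coordinates are re-laid out. ``pre_realized`` carries realized divergence
    accumulated on the focal lineage before the WGD (used when the ancestor
    passed in has already diverged from the speciation point).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    pre_realized = dict(pre_realized or {})
    truth = TruthTable()

    # per-chromosome ordered gene lists for the two subgenomes
    chrom_genes: dict[str, list[tuple[str, str, str]]] = {}
    cds: dict[str, str] = {}
    realized_branch: dict[str, float] = {}
    for seq_id in ancestor.seq_ids():
        for suffix in ("a", "b"):
            chrom_genes[seq_id + suffix] = []
    for g in sorted(ancestor.genes, key=lambda g: (g.seq_id, g.rank)):
        survive_a = rng.random() >= params.loss_probability
        survive_b = rng.random() >= params.loss_probability
        truth.loss_flags[g.gene_id] = (survive_a, survive_b)
        for suffix, survives in (("a", survive_a), ("b", survive_b)):
            if not survives:
                continue
            copy_id = g.gene_id + suffix
            evolved, realized = _evolve_cds(
                ancestor.cds[g.gene_id],
                params.wgd_branch_length,
                params.kappa,
                params.omega_sim,
                rng,
            )
            cds[copy_id] = evolved
            realized_branch[copy_id] = realized
            truth.focal_realized[copy_id] = realized + pre_realized.get(g.gene_id, 0.0)
            chrom_genes[g.seq_id + suffix].append((copy_id, evolved, g.strand))

    if all(len(v) == 0 for v in chrom_genes.values()):
        raise FormatError("no genes survived fractionation")

    for gid, (sa, sb) in truth.loss_flags.items():
        if sa and sb:
            pair = (gid + "a", gid + "b")
            truth.paralog_pairs[pair] = PairTruth(
                expected=2.0 * params.wgd_branch_length,
                realized=realized_branch[pair[0]] + realized_branch[pair[1]],
            )

    # segmental inversions: reverse gene order and flip strands
    seq_ids = sorted(chrom_genes)
    for _ in range(params.inversion_count):
        sid = seq_ids[int(rng.integers(len(seq_ids)))]
        block = chrom_genes[sid]
        if len(block) < 2:
            continue
        i, j = _pick_segment(len(block), rng)
        segment = [
            (gid, seq, "-" if strand == "+" else "+")
            for gid, seq, strand in reversed(block[i:j])
        ]
        chrom_genes[sid] = block[:i] + segment + block[j:]

    # translocations: move a segment to a random position on another chromosome
    for _ in range(params.translocation_count):
        donors = [s for s in seq_ids if len(chrom_genes[s]) >= 5]
        if len(donors) < 2:
            break
        src = donors[int(rng.integers(len(donors)))]
        dst_choices = [s for s in seq_ids if s != src]
        dst = dst_choices[int(rng.integers(len(dst_choices)))]
        i, j = _pick_segment(len(chrom_genes[src]), rng)
        segment = chrom_genes[src][i:j]
        chrom_genes[src] = chrom_genes[src][:i] + chrom_genes[src][j:]
        at = int(rng.integers(0, len(chrom_genes[dst]) + 1))
        chrom_genes[dst] = chrom_genes[dst][:at] + segment + chrom_genes[dst][at:]

    genes: list[GeneModel] = []
    chromosomes: dict[str, str] = {}
    for sid in seq_ids:
        placed, seq = _layout_chromosome(sid, chrom_genes[sid], params, rng)
        genes.extend(placed)
        chromosomes[sid] = seq
    focal = GenomeAnnotation.from_genes("focal", genes, cds, chromosomes)
    return focal, truth


def emit_outgroup(
    ancestor: GenomeAnnotation,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    truth: TruthTable | None = None,
) -> GenomeAnnotation:
    """Generate the outgroup genome: a single-copy relative split pre-WGD.

    Every ancestral gene is evolved along a branch of
    ``speciation_branch_length`` and re-laid out in the ancestral order as
    ``<id>o`` on ``ochr*``. When a TruthTable from ``apply_wgd_and_diverge``
    is given, ortholog pairs against each surviving focal copy are recorded
    with expected total divergence ``2 * speciation_branch_length``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    evolved, realized = _evolve_all(
        ancestor.cds, params.speciation_branch_length, params, rng
    )
    genes: list[GeneModel] = []
    cds: dict[str, str] = {}
    chromosomes: dict[str, str] = {}
    for seq_id in ancestor.seq_ids():
        ordered = []
        for g in ancestor.genes_on(seq_id):
            oid = g.gene_id + "o"
            cds[oid] = evolved[g.gene_id]
            ordered.append((oid, cds[oid], g.strand))
        placed, seq = _layout_chromosome("o" + seq_id, ordered, params, rng)
        genes.extend(placed)
        chromosomes["o" + seq_id] = seq
    outgroup = GenomeAnnotation.from_genes("outgroup", genes, cds, chromosomes)

    if truth is not None:
        for gid in truth.loss_flags:
            for copy_id in truth.surviving_focal_ids(gid):
                truth.ortholog_pairs[(gid + "o", copy_id)] = PairTruth(
                    expected=2.0 * params.speciation_branch_length,
                    realized=realized[gid] + truth.focal_realized[copy_id],
                )
    return outgroup


def simulate_paleotetraploid(params: EvolutionParams) -> SimulatedDataset:
    """End-to-end driver: ancestor -> (outgroup, pre-WGD branch -> WGD genome).

    The focal lineage receives a pre-WGD branch of
    ``speciation_branch_length - wgd_branch_length`` before duplication, so
    paralog pairs total ``2*wgd_branch_length`` and ortholog pairs total
    ``2*speciation_branch_length`` substitutions per 4D site.
    """
    if params.speciation_branch_length < params.wgd_branch_length:
        warnings.warn(
            "speciation branch shorter than WGD branch: the split would "
            "postdate the WGD; proceeding with a zero-length pre-WGD branch"
        )
    rng = np.random.default_rng(params.seed)
    ancestor = simulate_ancestor(params, rng)
    pre_branch = max(0.0, params.speciation_branch_length - params.wgd_branch_length)
    pre_cds, pre_realized = _evolve_all(ancestor.cds, pre_branch, params, rng)
    focal_pre = GenomeAnnotation.from_genes(
        "ancestor", ancestor.genes, pre_cds, ancestor.chromosomes
    )
    focal, truth = apply_wgd_and_diverge(focal_pre, params, rng, pre_realized)
    outgroup = emit_outgroup(ancestor, params, rng, truth)
    return SimulatedDataset(params, ancestor, focal, outgroup, truth)


def emit_synthetic_map(
    genome: GenomeAnnotation,
    markers_per_chromosome: int,
    rng: np.random.Generator | int | None = None,
    flank_length: int = 300,
    cm_per_mb: float = 4.0,
    jitter_sd: float = 0.0,
    fragments_per_chromosome: int = 4,
) -> tuple[list[MarkerRecord], dict[str, str], MapTruth]:
    """Derive a genetic map and a fragmented assembly from a genome.

    Each chromosome becomes one linkage group; cM positions are proportional
    to the physical position (``cm_per_mb``) plus optional Gaussian jitter.
    The chromosome sequences are cut into ``fragments_per_chromosome``
    scaffolds at near-even randomised breakpoints; scaffold names are
    shuffled and each scaffold is emitted reverse-complemented with
    probability 1/2. Marker flanks are taken from the forward strand of the
    unfragmented chromosome. Truth records each scaffold's linkage group,
    order and orientation.
    """
    if not genome.chromosomes:
        raise FormatError("genome carries no chromosome sequences")
    if markers_per_chromosome < 2:
        warnings.warn("fewer than 2 markers per chromosome: orientation untestable")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))

    seq_ids = sorted(genome.chromosomes)
    n_scaffolds = fragments_per_chromosome * len(seq_ids)
    name_order = rng.permutation(n_scaffolds)
    markers: list[MarkerRecord] = []
    scaffolds: dict[str, str] = {}
    truth = MapTruth()

    scaffold_counter = 0
    for lg, seq_id in enumerate(seq_ids, start=1):
        seq = genome.chromosomes[seq_id]
        length = len(seq)
        k = max(1, fragments_per_chromosome)
        base = length / k
        cuts = [0]
        for i in range(1, k):
            cuts.append(int(round(base * i + rng.uniform(-0.2, 0.2) * base)))
        cuts.append(length)
        marker_counter = 0
        for order, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
            name = f"scf{int(name_order[scaffold_counter]):04d}"
            scaffold_counter += 1
            piece = seq[lo:hi]
            orientation = "+" if rng.random() < 0.5 else "-"
            scaffolds[name] = piece if orientation == "+" else _revcomp(piece)
            truth.scaffolds[name] = (lg, order, orientation)
            # stratified marker placement within the fragment
            frac = (hi - lo) / length
            m_f = max(2, int(round(markers_per_chromosome * frac)))
            usable = hi - lo - flank_length
            if usable <= m_f:
                continue
            stride = usable / m_f
            for j in range(m_f):
                offset = lo + int(rng.integers(int(j * stride), int((j + 1) * stride)))
                flank = seq[offset : offset + flank_length]
                cm = offset * cm_per_mb / 1e6
                if jitter_sd > 0:
                    cm = max(0.0, cm + rng.normal(0.0, jitter_sd))
                marker_id = f"mk{lg:02d}_{marker_counter:04d}"
                marker_counter += 1
                markers.append(MarkerRecord(marker_id, lg, cm, flank))
                truth.markers[marker_id] = (seq_id, offset + 1)
    return markers, scaffolds, truth
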