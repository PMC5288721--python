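"""Configuration and end-to-end drivers tying the analysis stages together.

A run goes homology -> synteny -> per-pair divergence -> WGD inference
(plus optional genetic-map anchoring), either on a simulated paleotetraploid
dataset with known truth or on user-supplied annotation/sequence/hit files.
A YAML config with strict (unknown-key-rejecting) blocks describes a run;
a manifest with parameters, seed and input checksums is written next to the
outputs so any run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .anchoring import anchor_assembly, emit_agp
from .homology import SearchParams, align_global, all_vs_all
from .io_formats import (
    FormatError,
    GenomeAnnotation,
    HitTable,
    read_fasta,
    read_genetic_map,
    read_gff_genes,
    read_hits_tab,
    write_block_outputs,
    write_fasta,
    write_genetic_map,
    write_gff_genes,
    write_hits_tab,
)
from .molevol import DivergenceEstimate, backtranslate, estimate_divergence
from .synteny import ChainParams, SyntenyBlock, classify_homeology, find_synteny
from .synth_genome import (
    EvolutionParams,
    SimulatedDataset,
    emit_synthetic_map,
    expected_corrected_4dtv,
    expected_two_copy_fraction,
    simulate_paleotetraploid,
)
from .wgd_inference import (
    detect_peaks,
    order_events,
    retention_analysis,
    summarize_distribution,
)

__all__ = [
    "PipelineConfig",
    "PeakParams",
    "WgdResults",
    "block_pair_divergences",
    "run_wgd_analysis",
    "run_simulation_study",
    "true_pairs_in_runs",
]

logger = logging.getLogger("wgdkit")


@dataclass(frozen=True)
class PeakParams:
    bin_width: float = 0.01
    min_pairs: int = 50
    prominence_fraction: float = 0.1
    order_tolerance: float = 0.01


@dataclass
class InputPaths:
    """Real-data inputs; unset entries disable the corresponding stage."""

    annotation: str | None = None
    cds: str | None = None
    hits: str | None = None
    outgroup_annotation: str | None = None
    outgroup_cds: str | None = None
    cross_hits: str | None = None
    genetic_map: str | None = None
    assembly: str | None = None


@dataclass
class PipelineConfig:
    """One run: either simulator parameters or real input paths."""

    outdir: str = "wgdkit_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: EvolutionParams | None = None
    inputs: InputPaths | None = None
    search: SearchParams = field(default_factory=SearchParams)
    chain: ChainParams = field(default_factory=ChainParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    anchoring_gap_size: int = 100

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise FormatError(
                "config must set exactly one of 'simulate' and 'inputs'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data, name):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - fields
            if unknown:
                raise FormatError(f"unknown {name} keys: {sorted(unknown)}")
            return klass(**data)

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = build(EvolutionParams, kwargs["simulate"], "simulate")
        if "inputs" in kwargs and kwargs["inputs"] is not None:
            kwargs["inputs"] = build(InputPaths, kwargs["inputs"], "inputs")
        if "search" in kwargs:
            kwargs["search"] = build(SearchParams, kwargs["search"], "search")
        if "chain" in kwargs:
            kwargs["chain"] = build(ChainParams, kwargs["chain"], "chain")
        if "peaks" in kwargs:
            kwargs["peaks"] = build(PeakParams, kwargs["peaks"], "peaks")
        return cls(**kwargs)

    def validate_paths(self) -> None:
        if self.inputs is None:
            return
        for name, value in dataclasses.asdict(self.inputs).items():
            if value is not None and not Path(value).exists():
                raise FormatError(f"input {name}: file not found: {value}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# per-pair divergence over synteny blocks
# ---------------------------------------------------------------------------


def block_pair_divergences(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    blocks: Sequence[SyntenyBlock],
    search: SearchParams | None = None,
) -> list[DivergenceEstimate]:
    """4DTv and Ka/Ks for every distinct anchor pair of the blocks.

    Each pair is globally aligned at the protein level, back-translated to
    codons, and passed through the 4DTv and NG86 estimators.
    """
    search = search or SearchParams()
    seen: set[tuple[str, str]] = set()
    estimates: list[DivergenceEstimate] = []
    for block in blocks:
        for anchor in block.anchors:
            key = (anchor.gene_a, anchor.gene_b)
            if key in seen or (key[1], key[0]) in seen:
                continue
            seen.add(key)
            prot_a = ann_a.protein(anchor.gene_a)
            prot_b = ann_b.protein(anchor.gene_b)
            row_a, row_b = align_global(prot_a, prot_b, search)
            aln = backtranslate(
                row_a,
                row_b,
                ann_a.cds[anchor.gene_a],
                ann_b.cds[anchor.gene_b],
                anchor.gene_a,
                anchor.gene_b,
            )
            estimates.append(estimate_divergence(aln))
    return estimates


def write_divergence_tsv(
    estimates: Sequence[DivergenceEstimate], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tn_4d_sites\tfourdtv_raw\tfourdtv_corrected\t"
            "ka\tks\tka_ks\n"
        )
        for e in estimates:
            fh.write(
                f"{e.id_a}\t{e.id_b}\t{e.n_4d_sites}\t{e.fourdtv_raw:.6g}\t"
                f"{e.fourdtv_corrected:.6g}\t{e.ka:.6g}\t{e.ks:.6g}\t{e.ka_ks:.6g}\n"
            )
    return path


# ---------------------------------------------------------------------------
# end-to-end WGD analysis
# ---------------------------------------------------------------------------


@dataclass
class WgdResults:
    """Bundle of everything one WGD analysis run produced."""

    outdir: Path
    self_hits: HitTable
    self_blocks: list[SyntenyBlock]
    self_estimates: list[DivergenceEstimate]
    self_summary: object
    self_peaks: list
    homeology: object
    cross_hits: HitTable | None = None
    cross_blocks: list[SyntenyBlock] | None = None
    cross_estimates: list[DivergenceEstimate] | None = None
    cross_summary: object = None
    cross_peaks: list | None = None
    event_order: list | None = None
    retention: object = None
    dataset: SimulatedDataset | None = None
    manifest: dict = field(default_factory=dict)


def _load_real_inputs(config: PipelineConfig):
    inp = config.inputs
    ann = read_gff_genes(inp.annotation)
    ann.cds.update(read_fasta(inp.cds))
    outgroup = None
    if inp.outgroup_annotation:
        outgroup = read_gff_genes(inp.outgroup_annotation)
        if inp.outgroup_cds:
            outgroup.cds.update(read_fasta(inp.outgroup_cds))
        if outgroup.genome_id == ann.genome_id:
            outgroup.genome_id = ann.genome_id + "_outgroup"
    self_hits = read_hits_tab(inp.hits) if inp.hits else None
    cross_hits = read_hits_tab(inp.cross_hits) if inp.cross_hits else None
    return ann, outgroup, self_hits, cross_hits


def run_wgd_analysis(config: PipelineConfig) -> WgdResults:
    """Execute homology -> synteny -> divergence -> WGD inference.

    Deterministic for a fixed config and seed; every stage's outputs are
    written under ``config.outdir`` together with a run manifest.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "search": dataclasses.asdict(config.search),
            "chain": dataclasses.asdict(config.chain),
            "peaks": dataclasses.asdict(config.peaks),
        },
        "inputs": {},
    }

    dataset = None
    self_hits = cross_hits = None
    if config.simulate is not None:
        params = dataclasses.replace(config.simulate, seed=config.seed)
        manifest["config"]["simulate"] = dataclasses.asdict(params)
        logger.info("simulating paleotetraploid dataset (seed %d)", params.seed)
        dataset = simulate_paleotetraploid(params)
        ann, outgroup = dataset.focal, dataset.outgroup
        write_gff_genes(ann, outdir / "focal.gff3")
        write_fasta(ann.cds, outdir / "focal.cds.fasta")
        write_gff_genes(outgroup, outdir / "outgroup.gff3")
        write_fasta(outgroup.cds, outdir / "outgroup.cds.fasta")
    else:
        ann, outgroup, self_hits, cross_hits = _load_real_inputs(config)
        for name, value in dataclasses.asdict(config.inputs).items():
            if value:
                manifest["inputs"][name] = {
                    "path": str(value),
                    "sha256": _sha256(Path(value)),
                }

    try:
        # stage: homology
        if self_hits is None:
            logger.info("all-vs-all self search over %d genes", len(ann.genes))
            self_hits = all_vs_all(ann, None, config.search)
        write_hits_tab(self_hits, outdir / "self.hits.tsv")
        if outgroup is not None and cross_hits is None:
            logger.info("cross-genome search vs %s", outgroup.genome_id)
            cross_hits = all_vs_all(ann, outgroup, config.search)
        if cross_hits is not None:
            write_hits_tab(cross_hits, outdir / "cross.hits.tsv")

        # stage: synteny
        self_blocks = find_synteny(ann, ann, self_hits, config.chain)
        write_block_outputs(self_blocks, ann, ann, outdir, "self")
        groups = {seq: seq for seq in ann.seq_ids()}
        homeology = classify_homeology(self_blocks, groups)
        cross_blocks = None
        if cross_hits is not None:
            cross_blocks = find_synteny(ann, outgroup, cross_hits, config.chain)
            write_block_outputs(cross_blocks, ann, outgroup, outdir, "cross")

        # stage: divergence
        self_estimates = block_pair_divergences(ann, ann, self_blocks, config.search)
        write_divergence_tsv(self_estimates, outdir / "self.divergence.tsv")
        cross_estimates = None
        if cross_blocks is not None:
            cross_estimates = block_pair_divergences(
                ann, outgroup, cross_blocks, config.search
            )
            write_divergence_tsv(cross_estimates, outdir / "cross.divergence.tsv")

        # stage: WGD inference
        pk = config.peaks
        self_summary = summarize_distribution(
            self_estimates, "self", pk.bin_width, min_pairs=pk.min_pairs
        )
        self_peaks = detect_peaks(self_summary, pk.prominence_fraction)
        cross_summary = cross_peaks = event_order = retention = None
        if cross_estimates is not None:
            cross_summary = summarize_distribution(
                cross_estimates, "cross", pk.bin_width, min_pairs=pk.min_pairs
            )
            cross_peaks = detect_peaks(cross_summary, pk.prominence_fraction)
            event_order = order_events(
                {"self": self_peaks, "cross": cross_peaks},
                ["self"],
                ["cross"],
                pk.order_tolerance,
            )
            retention = retention_analysis(
                cross_hits,
                [g.gene_id for g in ann.genes],
                [g.gene_id for g in outgroup.genes],
            )
        for name, summary in (("self", self_summary), ("cross", cross_summary)):
            if summary is None:
                continue
            with open(outdir / f"{name}.4dtv_distribution.tsv", "w") as fh:
                fh.write("bin_start\tcount\tdensity\n")
                for edge, count, dens in summary.to_table():
                    fh.write(f"{edge:.3f}\t{count}\t{dens:.6g}\n")
        if retention is not None:
            with open(outdir / "retention.tsv", "w") as fh:
                fh.write("n_homologs\tn_outgroup_genes\n")
                for count in sorted(retention.counts):
                    fh.write(f"{count}\t{retention.counts[count]}\n")
        report = {
            "self_peaks": [dataclasses.asdict(p) for p in self_peaks],
            "cross_peaks": [dataclasses.asdict(p) for p in cross_peaks or []],
            "event_order": event_order,
            "homeology": [
                {"groups": [str(g) for g in c["groups"]], "label": c["label"]}
                for c in homeology.components
            ],
            "retention": None
            if retention is None
            else {
                "counts": retention.counts,
                "two_copy_percent": retention.two_copy_percent,
                "n_considered": retention.n_considered,
            },
        }
        (outdir / "wgd_report.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise FormatError(f"pipeline aborted: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return WgdResults(
        outdir=outdir,
        self_hits=self_hits,
        self_blocks=self_blocks,
        self_estimates=self_estimates,
        self_summary=self_summary,
        self_peaks=self_peaks,
        homeology=homeology,
        cross_hits=cross_hits,
        cross_blocks=cross_blocks,
        cross_estimates=cross_estimates,
        cross_summary=cross_summary,
        cross_peaks=cross_peaks,
        event_order=event_order,
        retention=retention,
        dataset=dataset,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# truth-vs-inferred comparison
# ---------------------------------------------------------------------------


def true_pairs_in_runs(
    dataset: SimulatedDataset, chain: ChainParams
) -> set[tuple[str, str]]:
    """True paralog pairs lying in surviving colinear runs of >= min_genes.

    With no rearrangements the focal subgenomes preserve ancestral order, so
    a run is a maximal stretch of both-copies-surviving ancestral genes in
    which consecutive surviving pairs are within the chaining gap limit on
    both subgenomes.
    """
    truth = dataset.truth
    qualifying: set[tuple[str, str]] = set()
    focal_rank = {g.gene_id: g.rank for g in dataset.focal.genes}
    for seq_id in dataset.ancestor.seq_ids():
        ordered = [g.gene_id for g in dataset.ancestor.genes_on(seq_id)]
        paired = [gid for gid in ordered if all(truth.loss_flags[gid])]
        run: list[str] = []
        runs: list[list[str]] = []
        for gid in paired:
            if run:
                prev = run[-1]
                gap_a = focal_rank[gid + "a"] - focal_rank[prev + "a"]
                gap_b = focal_rank[gid + "b"] - focal_rank[prev + "b"]
                if gap_a > chain.max_gap or gap_b > chain.max_gap:
                    runs.append(run)
                    run = []
            run.append(gid)
        if run:
            runs.append(run)
        for r in runs:
            if len(r) >= chain.min_genes:
                qualifying.update((gid + "a", gid + "b") for gid in r)
    return qualifying


def _block_pairs(blocks: Sequence[SyntenyBlock]) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for b in blocks:
        for a in b.anchors:
            out.add(tuple(sorted((a.gene_a, a.gene_b))))
    return out


def run_simulation_study(config: PipelineConfig, n_replicates: int) -> dict:
    """Replicated truth-vs-inferred comparison on simulated datasets.

    Per replicate: 4DTv peak-location error against the model expectation,
    synteny recall/precision against true paralog pairs (recall within the
    >= min_genes colinear stratum), retention-fraction error against the
    independent-loss closed form, and anchoring order/orientation accuracy.
    Replicate seeds derive deterministically from the master seed.
    """
    if n_replicates <= 0:
        raise FormatError("n_replicates must be positive")
    if config.simulate is None:
        raise FormatError("simulation study requires simulator parameters")
    rows: list[dict] = []
    for i in range(n_replicates):
        seed = (config.seed + 9973 * (i + 1)) % (2**31)
        rep_config = dataclasses.replace(
            config,
            seed=seed,
            outdir=str(Path(config.outdir) / f"rep{i:02d}"),
        )
        results = run_wgd_analysis(rep_config)
        ds = results.dataset
        params = ds.params
        expected_peak = expected_corrected_4dtv(
            2.0 * params.wgd_branch_length, params.kappa
        )
        peak_error = math.nan
        if results.self_peaks:
            nearest = min(
                results.self_peaks, key=lambda p: abs(p.location - expected_peak)
            )
            peak_error = abs(nearest.location - expected_peak)
        truth_pairs = {tuple(sorted(p)) for p in ds.truth.paralog_pairs}
        stratum = {tuple(sorted(p)) for p in true_pairs_in_runs(ds, config.chain)}
        found = _block_pairs(results.self_blocks)
        recall = (
            len(found & stratum) / len(stratum) if stratum else float("nan")
        )
        precision = (
            len(found & truth_pairs) / len(found) if found else float("nan")
        )
        retention_error = float("nan")
        if results.retention is not None:
            retention_error = abs(
                results.retention.two_copy_fraction
                - expected_two_copy_fraction(params.loss_probability)
            )
        # anchoring on the simulated focal genome, jitter-free
        markers, scaffolds, map_truth = emit_synthetic_map(
            ds.focal, markers_per_chromosome=12, rng=seed
        )
        _, placements = anchor_assembly(markers, scaffolds)
        order_ok = orientation_ok = 0
        for sp in placements:
            lg, order, orientation = map_truth.scaffolds[sp.scaffold_id]
            same_lg = [
                p for p in placements
                if map_truth.scaffolds[p.scaffold_id][0] == lg
            ]
            same_lg.sort(key=lambda p: (p.position, p.scaffold_id))
            if same_lg.index(sp) == order:
                order_ok += 1
            if sp.orientation == orientation:
                orientation_ok += 1
        rows.append(
            {
                "seed": seed,
                "peak_location_error": peak_error,
                "block_recall": recall,
                "block_precision": precision,
                "retention_fraction_error": retention_error,
                "anchoring_order_accuracy": order_ok / len(placements),
                "anchoring_orientation_accuracy": orientation_ok / len(placements),
            }
        )
    metrics = [k for k in rows[0] if k != "seed"]
    aggregate = {
        k: {
            "mean": float(np.nanmean([r[k] for r in rows])),
            "sd": float(np.nanstd([r[k] for r in rows])),
        }
        for k in metrics
    }
    return {"replicates": rows, "aggregate": aggregate}
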