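"""Colinear synteny-block detection in gene-rank space.

Homologous gene pairs (anchors) are projected into the rank space of two
gene orders and chained by dynamic programming into colinear runs, under the
criterion used for paleotetraploidy evidence: a block needs at least
``min_genes`` syntenic gene pairs, with at most ``max_intervening`` genes
between consecutive pairs on either side (a rank gap of at most
``max_intervening + 1``), in either orientation.

Chains are scored by summed anchor bit scores with hard gap constraints (no
gap penalty). Blocks are extracted greedily: the best-scoring valid chain is
accepted, its anchors become unavailable, and the search repeats until the
best remaining chain falls below ``min_genes``. Ties are broken by total
score, then chain length, then the smaller (rank_a, rank_b) start, then
parallel before antiparallel — the output is deterministic.

Tandem arrays (homologous genes within ``tandem_window`` ranks of each other
on one sequence hitting the same partner) are collapsed to their best-
scoring member before chaining, so an array does not masquerade as a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .io_formats import FormatError, GenomeAnnotation, HitTable

__all__ = [
    "ChainParams",
    "Anchor",
    "SyntenyBlock",
    "HomeologySummary",
    "build_anchors",
    "chain_blocks",
    "find_synteny",
    "classify_homeology",
]


@dataclass(frozen=True)
class ChainParams:
    """Chaining criterion: block size, gap tolerance, orientations."""

    min_genes: int = 10
    max_intervening: int = 6
    allow_inversions: bool = True
    tandem_window: int = 5

    def __post_init__(self) -> None:
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")

    @property
    def max_gap(self) -> int:
        """Largest allowed rank difference between consecutive anchors."""
        return self.max_intervening + 1


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair in rank space."""

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass
class SyntenyBlock:
    """A chained colinear run of anchors between two sequences."""

    anchors: list[Anchor]
    orientation: str  # parallel | antiparallel
    seq_a: str
    seq_b: str

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)

    def __len__(self) -> int:
        return len(self.anchors)

    def validate(self, params: ChainParams) -> None:
        if len(self.anchors) < params.min_genes:
            raise FormatError("block below min_genes")
        for prev, cur in zip(self.anchors, self.anchors[1:]):
            da = cur.rank_a - prev.rank_a
            db = cur.rank_b - prev.rank_b
            if not (1 <= da <= params.max_gap):
                raise FormatError(f"rank_a gap {da} outside [1, {params.max_gap}]")
            if self.orientation == "parallel":
                if not (1 <= db <= params.max_gap):
                    raise FormatError(f"rank_b gap {db} outside [1, {params.max_gap}]")
            else:
                if not (1 <= -db <= params.max_gap):
                    raise FormatError(f"rank_b gap {-db} outside [1, {params.max_gap}]")


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _collapse_tandems(
    anchors: list[Anchor], side: str, window: int
) -> list[Anchor]:
    """Merge anchors whose genes on one side form a tandem array.

    Anchors sharing the partner gene on the *other* side, lying on the same
    sequence of this side within ``window`` ranks of each other, are replaced
    by the highest-scoring member (ties by gene ids).
    """
    groups: dict[tuple, list[Anchor]] = {}
    for a in anchors:
        key = (a.gene_b, a.seq_a) if side == "a" else (a.gene_a, a.seq_b)
        groups.setdefault(key, []).append(a)
    kept: list[Anchor] = []
    for members in groups.values():
        members.sort(key=lambda a: a.rank_a if side == "a" else a.rank_b)
        cluster: list[Anchor] = []
        prev_rank: int | None = None
        for a in members:
            rank = a.rank_a if side == "a" else a.rank_b
            if prev_rank is not None and rank - prev_rank > window:
                kept.append(
                    max(cluster, key=lambda x: (x.score, x.gene_a, x.gene_b))
                )
                cluster = []
            cluster.append(a)
            prev_rank = rank
        if cluster:
            kept.append(max(cluster, key=lambda x: (x.score, x.gene_a, x.gene_b)))
    return kept


def build_anchors(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    hits: HitTable,
    params: ChainParams | None = None,
) -> list[Anchor]:
    """Project retained hits into rank space and collapse tandem arrays.

    In self-genome mode (the two annotations are the same genome) self-pairs
    are excluded and each unordered gene pair is kept once, oriented so that
    side a holds the gene with the smaller (seq_id, rank).
    """
    params = params or ChainParams()
    self_mode = ann_a is ann_b or ann_a.genome_id == ann_b.genome_id
    genes_a = ann_a.by_id()
    genes_b = ann_b.by_id()

    best: dict[tuple[str, str], Anchor] = {}
    for rec in hits:
        if rec.is_self_hit:
            continue
        if rec.query_id not in genes_a:
            if self_mode:
                raise FormatError(f"hit references unknown gene {rec.query_id}")
            continue  # mirrored row of a cross table; counted from the other side
        if rec.subject_id not in genes_b:
            raise FormatError(f"hit references unknown gene {rec.subject_id}")
        ga, gb = genes_a[rec.query_id], genes_b[rec.subject_id]
        if self_mode and (gb.seq_id, gb.rank) < (ga.seq_id, ga.rank):
            ga, gb = gb, ga
        key = (ga.gene_id, gb.gene_id)
        if key not in best or rec.bit_score > best[key].score:
            best[key] = Anchor(
                ga.gene_id, gb.gene_id, ga.seq_id, gb.seq_id, ga.rank, gb.rank,
                rec.bit_score,
            )
    anchors = list(best.values())
    anchors = _collapse_tandems(anchors, "a", params.tandem_window)
    anchors = _collapse_tandems(anchors, "b", params.tandem_window)
    anchors.sort(key=lambda a: (a.seq_a, a.seq_b, a.rank_a, a.rank_b))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _best_chain(
    anchors: list[Anchor], orientation: str, max_gap: int
) -> tuple[list[int], float] | None:
    """Highest-scoring valid chain (as anchor indices) in one orientation.

    Ties prefer longer chains, then the chain whose start anchor has the
    smaller (rank_a, rank_b).
    """
    order = sorted(
        range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b)
    )
    sign = 1 if orientation == "parallel" else -1
    # dp key per anchor: (score, length, -start_rank_a, -start_rank_b); maximised
    best_key: list[tuple] = [()] * len(anchors)
    back: list[int | None] = [None] * len(anchors)
    for pos, i in enumerate(order):
        ai = anchors[i]
        key = (ai.score, 1, -ai.rank_a, -ai.rank_b)
        pred = None
        for j in order[:pos]:
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if not (1 <= da <= max_gap and 1 <= db <= max_gap):
                continue
            cand = (
                best_key[j][0] + ai.score,
                best_key[j][1] + 1,
                best_key[j][2],
                best_key[j][3],
            )
            if cand > key:
                key, pred = cand, j
        best_key[i] = key
        back[i] = pred
    if not anchors:
        return None
    end = max(range(len(anchors)), key=lambda i: best_key[i])
    chain: list[int] = []
    cur: int | None = end
    while cur is not None:
        chain.append(cur)
        cur = back[cur]
    chain.reverse()
    return chain, best_key[end][0]


def _chain_sort_key(anchors: list[Anchor], chain: list[int], orientation: str):
    score = sum(anchors[i].score for i in chain)
    start = anchors[chain[0]]
    return (score, len(chain), -start.rank_a, -start.rank_b, orientation == "parallel")


def chain_blocks(
    anchors: Sequence[Anchor], params: ChainParams | None = None
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks, per sequence pair.

    Greedy extraction with anchor exclusivity: repeatedly take the best
    remaining chain (both orientations searched when ``allow_inversions``)
    and stop when it falls below ``min_genes``.
    """
    params = params or ChainParams()
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.seq_a, a.seq_b), []).append(a)

    orientations = ["parallel"]
    if params.allow_inversions:
        orientations.append("antiparallel")

    blocks: list[SyntenyBlock] = []
    for (seq_a, seq_b) in sorted(by_pair):
        remaining = sorted(by_pair[(seq_a, seq_b)], key=lambda a: (a.rank_a, a.rank_b))
        while remaining:
            candidates = []
            for orientation in orientations:
                found = _best_chain(remaining, orientation, params.max_gap)
                if found is not None:
                    chain, _score = found
                    candidates.append((orientation, chain))
            if not candidates:
                break
            orientation, chain = max(
                candidates, key=lambda c: _chain_sort_key(remaining, c[1], c[0])
            )
            if len(chain) < params.min_genes:
                break
            chosen = [remaining[i] for i in chain]
            block = SyntenyBlock(chosen, orientation, seq_a, seq_b)
            block.validate(params)
            blocks.append(block)
            used = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
    blocks.sort(key=lambda b: (b.seq_a, b.seq_b, b.anchors[0].rank_a, b.anchors[0].rank_b))
    return blocks


def find_synteny(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    hits: HitTable,
    params: ChainParams | None = None,
) -> list[SyntenyBlock]:
    """Anchor building plus chaining in one call."""
    params = params or ChainParams()
    return chain_blocks(build_anchors(ann_a, ann_b, hits, params), params)


# ---------------------------------------------------------------------------
# homeology patterns among linkage groups
# ---------------------------------------------------------------------------


@dataclass
class HomeologySummary:
    """Connected components of the linkage-group synteny graph."""

    components: list[dict] = field(default_factory=list)
    #: summed anchor counts per unordered LG pair
    pair_weights: dict[tuple, int] = field(default_factory=dict)

    @property
    def one_to_one_pairs(self) -> list[tuple]:
        return [
            tuple(c["groups"]) for c in self.components if c["label"] == "1:1 pair"
        ]


def classify_homeology(
    blocks: Sequence[SyntenyBlock],
    groups: Mapping[str, object],
    dominance_fraction: float = 0.8,
) -> HomeologySummary:
    """Classify linkage-group relations from genome-vs-self blocks.

    An undirected graph over linkage groups is weighted by summed anchor
    counts. A connected component of two groups whose mutual weight is at
    least ``dominance_fraction`` of each group's total is a "1:1 pair";
    larger components are "complex"; groups whose blocks all stay within one
    group are "isolated".
    """
    summary = HomeologySummary()
    graph = nx.Graph()
    totals: dict[object, int] = {}
    for block in blocks:
        for seq in (block.seq_a, block.seq_b):
            if seq not in groups:
                raise FormatError(f"block references sequence {seq} absent from groups map")
        lg_a, lg_b = groups[block.seq_a], groups[block.seq_b]
        n = len(block.anchors)
        totals[lg_a] = totals.get(lg_a, 0) + n
        totals[lg_b] = totals.get(lg_b, 0) + n
        key = tuple(sorted((lg_a, lg_b), key=repr))
        summary.pair_weights[key] = summary.pair_weights.get(key, 0) + n
        graph.add_node(lg_a)
        graph.add_node(lg_b)
        if lg_a != lg_b:
            w = graph.get_edge_data(lg_a, lg_b, {}).get("weight", 0)
            graph.add_edge(lg_a, lg_b, weight=w + n)

    for component in nx.connected_components(graph):
        lgs = sorted(component, key=repr)
        if len(lgs) == 1:
            label = "isolated"
        elif len(lgs) == 2:
            weight = graph[lgs[0]][lgs[1]]["weight"]
            if all(weight >= dominance_fraction * totals[lg] for lg in lgs):
                label = "1:1 pair"
            else:
                label = "complex"
        else:
            label = "complex"
        summary.components.append(
            {
                "groups": lgs,
                "label": label,
                "weights": {
                    pair: w
                    for pair, w in summary.pair_weights.items()
                    if pair[0] in lgs or pair[1] in lgs
                },
            }
        )
    summary.components.sort(key=lambda c: [repr(g) for g in c["groups"]])
    return summary
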