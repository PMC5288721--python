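"""Scaffold anchoring onto a genetic linkage map.

Marker flanking sequences are located in the assembly by exact substring
search (forward and reverse complement). A marker found exactly once is a
unique placement; scaffolds are assigned the linkage group carrying the
majority of their unique markers (conflicts flagged), ordered within the
group by median cM, and oriented by the sign of the rank correlation between
marker offset and cM — a scaffold needs at least two markers with distinct
genetic positions to be orientable. Results are emitted as AGP v2.1
pseudomolecule objects plus a summary of anchored/oriented counts and
lengths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import FormatError, MarkerRecord

__all__ = [
    "MarkerPlacement",
    "ScaffoldPlacement",
    "locate_markers",
    "assign_order",
    "orient_scaffolds",
    "emit_agp",
    "read_agp",
    "anchor_assembly",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkerPlacement:
    """Where one marker's flank lands in the assembly."""

    marker_id: str
    status: str  # unique | ambiguous | unplaced
    scaffold_id: str | None = None
    offset: int | None = None  # 1-based position of the flank start
    match_strand: str | None = None


@dataclass
class ScaffoldPlacement:
    """A scaffold's assigned linkage group, position and orientation."""

    scaffold_id: str
    linkage_group: int
    position: float  # median cM of supporting markers
    orientation: str = "unoriented"  # + | - | unoriented
    n_markers: int = 0
    conflict: bool = False


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def locate_markers(
    markers: Sequence[MarkerRecord], scaffolds: Mapping[str, str]
) -> list[MarkerPlacement]:
    """Exact search of each flank (and reverse complement) in all scaffolds.

    Exactly one occurrence in total -> unique (with strand); more ->
    ambiguous; none -> unplaced. Statuses capture outcomes; nothing raises.
    """
    upper = {sid: seq.upper() for sid, seq in scaffolds.items()}
    placements: list[MarkerPlacement] = []
    for marker in markers:
        flank = marker.flank.upper()
        rc = _revcomp(flank)
        occurrences: list[tuple[str, int, str]] = []
        for sid in sorted(upper):
            seq = upper[sid]
            occurrences.extend((sid, pos, "+") for pos in _find_all(seq, flank))
            if rc != flank:
                occurrences.extend((sid, pos, "-") for pos in _find_all(seq, rc))
        if len(occurrences) == 1:
            sid, pos, strand = occurrences[0]
            placements.append(
                MarkerPlacement(marker.marker_id, "unique", sid, pos + 1, strand)
            )
        elif occurrences:
            placements.append(MarkerPlacement(marker.marker_id, "ambiguous"))
        else:
            placements.append(MarkerPlacement(marker.marker_id, "unplaced"))
    return placements


def _unique_by_scaffold(
    placements: Sequence[MarkerPlacement], markers: Sequence[MarkerRecord]
) -> dict[str, list[tuple[MarkerRecord, MarkerPlacement]]]:
    by_id = {m.marker_id: m for m in markers}
    out: dict[str, list[tuple[MarkerRecord, MarkerPlacement]]] = {}
    for p in placements:
        if p.status != "unique":
            continue
        marker = by_id.get(p.marker_id)
        if marker is None:
            raise FormatError(f"placement references unknown marker {p.marker_id}")
        out.setdefault(p.scaffold_id, []).append((marker, p))
    return out


def assign_order(
    placements: Sequence[MarkerPlacement], markers: Sequence[MarkerRecord]
) -> list[ScaffoldPlacement]:
    """Assign each scaffold its majority linkage group and order by median cM.

    A scaffold with unique markers on more than one linkage group keeps the
    majority group (ties to the smaller group number) with the conflict flag
    set. The returned list is sorted by (linkage group, median cM,
    scaffold id).
    """
    grouped = _unique_by_scaffold(placements, markers)
    out: list[ScaffoldPlacement] = []
    for sid in sorted(grouped):
        support = grouped[sid]
        votes = Counter(m.linkage_group for m, _ in support)
        top_count = max(votes.values())
        lg = min(g for g, c in votes.items() if c == top_count)
        on_lg = [m.position for m, _ in support if m.linkage_group == lg]
        out.append(
            ScaffoldPlacement(
                scaffold_id=sid,
                linkage_group=lg,
                position=float(np.median(on_lg)),
                n_markers=len(support),
                conflict=len(votes) > 1,
            )
        )
    out.sort(key=lambda s: (s.linkage_group, s.position, s.scaffold_id))
    return out


def orient_scaffolds(
    placements: Sequence[MarkerPlacement],
    markers: Sequence[MarkerRecord],
    scaffold_placements: Sequence[ScaffoldPlacement],
) -> list[ScaffoldPlacement]:
    """Fill orientations from the offset-vs-cM rank correlation.

    Only markers on the scaffold's assigned linkage group vote. Fewer than
    two distinct cM values, or a zero correlation, leaves the scaffold
    unoriented (more than one SNP with a distinct genetic position is
    required to orient).
    """
    grouped = _unique_by_scaffold(placements, markers)
    out: list[ScaffoldPlacement] = []
    for sp in scaffold_placements:
        support = [
            (m, p)
            for m, p in grouped.get(sp.scaffold_id, [])
            if m.linkage_group == sp.linkage_group
        ]
        orientation = "unoriented"
        positions = [m.position for m, _ in support]
        if len(support) >= 2 and len(set(positions)) >= 2:
            offsets = [p.offset for _, p in support]
            if len(set(offsets)) >= 2:
                rho = stats.spearmanr(offsets, positions).statistic
                if rho > 0:
                    orientation = "+"
                elif rho < 0:
                    orientation = "-"
        out.append(
            ScaffoldPlacement(
                scaffold_id=sp.scaffold_id,
                linkage_group=sp.linkage_group,
                position=sp.position,
                orientation=orientation,
                n_markers=sp.n_markers,
                conflict=sp.conflict,
            )
        )
    return out


def emit_agp(
    placements: Sequence[ScaffoldPlacement],
    scaffold_lengths: Mapping[str, int],
    path: str | Path,
    gap_size: int = 100,
    total_assembly_length: int | None = None,
    lg_prefix: str = "LG",
) -> dict:
    """Write AGP v2.1 pseudomolecules and return an anchoring summary.

    One object per linkage group; scaffolds appear in placement order,
    separated by ``gap_size`` unknown gaps; unoriented scaffolds carry
    orientation "?". The summary reports anchored/oriented scaffold counts
    and lengths, the oriented share of anchored sequence, and (when the
    total assembly length is given) the anchored share of the assembly, all
    percentages to one decimal.
    """
    path = Path(path)
    by_lg: dict[int, list[ScaffoldPlacement]] = {}
    for sp in placements:
        if sp.scaffold_id not in scaffold_lengths:
            raise FormatError(f"no length for scaffold {sp.scaffold_id}")
        by_lg.setdefault(sp.linkage_group, []).append(sp)

    anchored_len = oriented_len = 0
    n_oriented = 0
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for lg in sorted(by_lg):
            obj = f"{lg_prefix}{lg}"
            coord = 0
            part = 0
            ordered = sorted(by_lg[lg], key=lambda s: (s.position, s.scaffold_id))
            for i, sp in enumerate(ordered):
                if i > 0:
                    part += 1
                    fh.write(
                        f"{obj}\t{coord + 1}\t{coord + gap_size}\t{part}\tU\t"
                        f"{gap_size}\tscaffold\tyes\tmap\n"
                    )
                    coord += gap_size
                length = scaffold_lengths[sp.scaffold_id]
                part += 1
                orient = sp.orientation if sp.orientation in "+-" else "?"
                fh.write(
                    f"{obj}\t{coord + 1}\t{coord + length}\t{part}\tW\t"
                    f"{sp.scaffold_id}\t1\t{length}\t{orient}\n"
                )
                coord += length
                anchored_len += length
                if orient in "+-":
                    oriented_len += length
                    n_oriented += 1
    n_anchored = sum(len(v) for v in by_lg.values())
    summary = {
        "anchored_scaffolds": n_anchored,
        "anchored_length": anchored_len,
        "oriented_scaffolds": n_oriented,
        "oriented_length": oriented_len,
        "oriented_share_percent": (
            round(100.0 * oriented_len / anchored_len, 1) if anchored_len else 0.0
        ),
    }
    if total_assembly_length:
        summary["assembly_length"] = total_assembly_length
        summary["anchored_share_percent"] = round(
            100.0 * anchored_len / total_assembly_length, 1
        )
    return summary


def read_agp(path: str | Path) -> list[ScaffoldPlacement]:
    """Re-read an AGP file into placements (order encoded via position index)."""
    path = Path(path)
    out: list[ScaffoldPlacement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 AGP columns")
            if cols[4] != "W":
                continue
            obj = cols[0]
            lg = int("".join(ch for ch in obj if ch.isdigit()) or 0)
            orientation = cols[8] if cols[8] in "+-" else "unoriented"
            out.append(
                ScaffoldPlacement(
                    scaffold_id=cols[5],
                    linkage_group=lg,
                    position=float(len([s for s in out if s.linkage_group == lg])),
                    orientation=orientation,
                )
            )
    return out


def anchored_gene_share(
    annotation, anchored_seq_ids: Sequence[str] | set
) -> float:
    """Percent of annotated genes sitting on anchored scaffolds (1 decimal)."""
    anchored_seq_ids = set(anchored_seq_ids)
    total = len(annotation.genes)
    if total == 0:
        raise FormatError("annotation has no genes")
    on_anchored = sum(1 for g in annotation.genes if g.seq_id in anchored_seq_ids)
    return round(100.0 * on_anchored / total, 1)


def anchor_assembly(
    markers: Sequence[MarkerRecord], scaffolds: Mapping[str, str]
) -> tuple[list[MarkerPlacement], list[ScaffoldPlacement]]:
    """Locate, assign and orient in one call."""
    marker_placements = locate_markers(markers, scaffolds)
    ordered = assign_order(marker_placements, markers)
    oriented = orient_scaffolds(marker_placements, markers, ordered)
    return marker_placements, oriented
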