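"""Codon-level divergence statistics for homologous gene pairs.

Implements back-translation of protein alignments to codon alignments,
identification of fourfold-degenerate (4D) sites, the 4DTv statistic (the
proportion of 4D third-codon positions that differ by a transversion) with a
Kimura transversion-component correction, and the Nei–Gojobori (1986)
counting estimator of Ka and Ks with equal-weight pathway averaging and the
Jukes–Cantor multiple-hit correction.

The 4DTv correction adopted is ``-1/2 * ln(1 - 2v)`` applied to the raw
transversion proportion v; under a two-parameter (Kimura) substitution model
this is the exact inverse of the expected transversion proportion, and it is
monotone in v, so peak locations are preserved under any alternative
monotone correction. The raw proportion is always reported alongside the
corrected value so results can be re-corrected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import FormatError

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "FOURFOLD_PREFIXES",
    "backtranslate",
    "fourfold_sites",
    "four_dtv",
    "ng86",
    "estimate_divergence",
    "family_kaks_compare",
]

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            from Bio.Seq import Seq as _Seq

            _CODON_TABLE[_codon] = str(_Seq(_codon).translate())

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in _CODON_TABLE if c not in STOP_CODONS))

#: two-base prefixes for which the amino acid is independent of the third base
FOURFOLD_PREFIXES = frozenset(
    p
    for p in (a + b for a in _BASES for b in _BASES)
    if len({_CODON_TABLE[p + b3] for b3 in _BASES}) == 1
    and (p + "A") not in STOP_CODONS
)

_PURINES = frozenset("AG")


def is_transversion(a: str, b: str) -> bool:
    """True when a!=b and exactly one of the two bases is a purine."""
    return a != b and ((a in _PURINES) != (b in _PURINES))


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """An aligned pair of coding sequences, in whole-codon columns."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise FormatError("codon rows differ in length")
        for row in (self.codons_a, self.codons_b):
            for i, c in enumerate(row):
                if len(c) != 3:
                    raise FormatError(f"column {i}: codon {c!r} is not a triplet")
                if c != "---" and "-" in c:
                    raise FormatError(f"column {i}: partial gap {c!r}")

    def __len__(self) -> int:
        return len(self.codons_a)

    def ungapped_columns(self) -> list[int]:
        return [
            i
            for i in range(len(self))
            if self.codons_a[i] != "---" and self.codons_b[i] != "---"
        ]


@dataclass
class DivergenceEstimate:
    """Per-pair divergence summary.

    ``fourdtv_corrected`` is NaN when saturated (raw >= 1/2) or when no 4D
    site exists; ``ka_ks`` is NaN when Ks is zero or undefined. The boolean
    flags make the reason explicit.
    """

    id_a: str
    id_b: str
    n_4d_sites: int = 0
    n_4d_transversions: int = 0
    fourdtv_raw: float = math.nan
    fourdtv_corrected: float = math.nan
    fourdtv_saturated: bool = False
    ka: float = math.nan
    ks: float = math.nan
    ka_ks: float = math.nan
    ka_saturated: bool = False
    ks_saturated: bool = False

    @property
    def fourdtv_defined(self) -> bool:
        return not math.isnan(self.fourdtv_corrected)

    @property
    def ka_ks_defined(self) -> bool:
        return not math.isnan(self.ka_ks)


def backtranslate(
    aligned_a: str,
    aligned_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Expand a pairwise protein alignment to a codon alignment.

    Each aligned residue is replaced by its source codon; residue gaps become
    gap triplets. Every ungapped residue must match the translation of its
    codon, otherwise an error naming the position is raised.
    """
    if len(aligned_a) != len(aligned_b):
        raise FormatError("aligned rows differ in length")

    def expand(aligned: str, cds: str, name: str) -> list[str]:
        cds = cds.upper()
        codons: list[str] = []
        pos = 0
        for col, residue in enumerate(aligned):
            if residue == "-":
                codons.append("---")
                continue
            codon = cds[3 * pos : 3 * pos + 3]
            if len(codon) < 3:
                raise FormatError(f"{name}: CDS exhausted at residue {pos}")
            translated = _CODON_TABLE.get(codon, "X")
            if translated != residue.upper():
                raise FormatError(
                    f"{name}: residue {pos} ({residue}) does not match codon "
                    f"{codon} ({translated}) at alignment column {col}"
                )
            codons.append(codon)
            pos += 1
        if 3 * pos != len(cds):
            raise FormatError(f"{name}: {len(cds) - 3 * pos} CDS bases left unused")
        return codons

    return CodonAlignment(
        id_a, id_b, expand(aligned_a, cds_a, id_a), expand(aligned_b, cds_b, id_b)
    )


def translate_alignment(aln: CodonAlignment) -> tuple[str, str]:
    """Back-map a codon alignment to the protein alignment it encodes."""

    def row(codons: list[str]) -> str:
        return "".join("-" if c == "---" else _CODON_TABLE.get(c, "X") for c in codons)

    return row(aln.codons_a), row(aln.codons_b)


# ---------------------------------------------------------------------------
# 4DTv
# ---------------------------------------------------------------------------


def fourfold_sites(aln: CodonAlignment) -> list[int]:
    """Codon columns whose third position is fourfold degenerate in both rows.

    A column qualifies when neither row is a gap, the first two codon
    positions are identical between the rows, and that shared two-base prefix
    determines the amino acid regardless of the third base. Columns with
    ambiguity codes are excluded.
    """
    sites: list[int] = []
    for i in aln.ungapped_columns():
        ca, cb = aln.codons_a[i], aln.codons_b[i]
        if any(base not in "ACGT" for base in ca + cb):
            continue
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites.append(i)
    return sites


def four_dtv(aln: CodonAlignment) -> DivergenceEstimate:
    """Raw and corrected 4DTv for one codon alignment.

    raw = transversion-differing 4D sites / eligible 4D sites; sites whose
    third bases differ only by a transition stay in the denominator.
    corrected = -1/2 ln(1 - 2 raw) for raw < 1/2, saturated otherwise.
    With zero eligible sites both values are NaN (undefined, not an error).
    """
    est = DivergenceEstimate(aln.id_a, aln.id_b)
    sites = fourfold_sites(aln)
    est.n_4d_sites = len(sites)
    if not sites:
        return est
    ntv = sum(
        1 for i in sites if is_transversion(aln.codons_a[i][2], aln.codons_b[i][2])
    )
    est.n_4d_transversions = ntv
    raw = ntv / len(sites)
    est.fourdtv_raw = raw
    if raw < 0.5:
        est.fourdtv_corrected = -0.5 * math.log(1.0 - 2.0 * raw)
    else:
        est.fourdtv_saturated = True
    return est


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    At each position the synonymous fraction is the share of the three
    possible single-base changes that preserve the amino acid; changes that
    create a stop codon count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and _CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at more than one position are resolved by averaging over
    all orderings of the single-base steps (minimal pathways), excluding any
    pathway that passes through a stop codon. In the degenerate case where
    every pathway is blocked by stops, all pathways are averaged instead.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn

    pathways = [walk(order) for order in itertools.permutations(diff_positions)]
    valid = [p for p in pathways if p is not None]
    if not valid:
        # all minimal pathways pass through stops; fall back to counting
        # through them (rare; documented behaviour)
        valid = []
        for order in itertools.permutations(diff_positions):
            syn = nonsyn = 0.0
            current = codon_a
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                aa_from = _CODON_TABLE[current]
                aa_to = _CODON_TABLE[nxt]
                if aa_from == aa_to:
                    syn += 1.0
                else:
                    nonsyn += 1.0
                current = nxt
            valid.append((syn, nonsyn))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86(aln: CodonAlignment) -> DivergenceEstimate:
    """Nei–Gojobori (1986) Ka and Ks for one codon alignment.

    Site counts are averaged over the two sequences; observed differences are
    partitioned by equal-weight pathway averaging; proportions are corrected
    with the one-parameter (Jukes–Cantor) multiple-hit formula. Columns with
    gaps, stops or ambiguity codes are excluded.
    """
    est = DivergenceEstimate(aln.id_a, aln.id_b)
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    used = 0
    for i in aln.ungapped_columns():
        ca, cb = aln.codons_a[i], aln.codons_b[i]
        if any(base not in "ACGT" for base in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsyn, dnon = _pair_differences(ca, cb)
        sd += dsyn
        nd += dnon
        used += 1
    if used == 0:
        raise FormatError(f"{aln.id_a}/{aln.id_b}: no usable codon columns")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    est.ks, est.ks_saturated = _jukes_cantor(ps)
    est.ka, est.ka_saturated = _jukes_cantor(pn)
    if not math.isnan(est.ks) and not math.isnan(est.ka) and est.ks > 0:
        est.ka_ks = est.ka / est.ks
    return est


def estimate_divergence(aln: CodonAlignment) -> DivergenceEstimate:
    """Full per-pair estimate: 4DTv fields plus NG86 Ka/Ks."""
    est = four_dtv(aln)
    kaks = ng86(aln)
    est.ka, est.ks, est.ka_ks = kaks.ka, kaks.ks, kaks.ka_ks
    est.ka_saturated, est.ks_saturated = kaks.ka_saturated, kaks.ks_saturated
    return est


# ---------------------------------------------------------------------------
# family-level Ka/Ks comparison
# ---------------------------------------------------------------------------


def family_kaks_compare(
    estimates: Sequence[DivergenceEstimate],
    family_labels: Mapping[tuple[str, str], str],
    reference: str | None = None,
) -> dict:
    """Compare mean Ka/Ks of gene-pair families against a reference set.

    ``family_labels`` maps (id_a, id_b) pairs to family names; unlabeled pairs
    belong to the background. The reference is the family named by
    ``reference``, or all defined Ka/Ks values when None (genome-wide mean).
    Each family is compared against the reference with a two-tailed Welch
    (unequal-variance) t-test. Families with fewer than two defined values
    are skipped with a warning entry.
    """
    import warnings

    values: dict[str, list[float]] = {}
    all_values: list[float] = []
    for est in estimates:
        if not est.ka_ks_defined:
            continue
        label = family_labels.get((est.id_a, est.id_b)) or family_labels.get(
            (est.id_b, est.id_a)
        )
        all_values.append(est.ka_ks)
        if label is not None:
            values.setdefault(label, []).append(est.ka_ks)

    if reference is None:
        ref_values = all_values
        ref_name = "genome-wide"
    else:
        ref_values = values.get(reference, [])
        ref_name = reference
    if len(ref_values) < 2:
        raise FormatError(f"reference group {ref_name!r} has fewer than 2 values")

    report: dict = {
        "reference": ref_name,
        "reference_n": len(ref_values),
        "reference_mean": float(np.mean(ref_values)),
        "genome_wide_mean": float(np.mean(all_values)) if all_values else math.nan,
        "families": {},
        "skipped": [],
    }
    for family in sorted(values):
        if family == reference:
            continue
        vals = values[family]
        if len(vals) < 2:
            warnings.warn(f"family {family}: fewer than 2 defined Ka/Ks values; skipped")
            report["skipped"].append(family)
            continue
        if np.var(vals) == 0.0 and np.var(ref_values) == 0.0:
            # degenerate case: no within-group variance; equal means -> no
            # evidence of difference, unequal means -> certain difference
            equal = math.isclose(float(np.mean(vals)), float(np.mean(ref_values)))
            t, p = (0.0, 1.0) if equal else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(vals, ref_values, equal_var=False)
        report["families"][family] = {
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "t": float(t),
            "p": float(p),
        }
    return report
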