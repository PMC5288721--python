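"""Codon statistics: back-translation, 4D sites, 4DTv, NG86, Ka/Ks t-tests."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from wgdkit import (
    CodonAlignment,
    EvolutionParams,
    FormatError,
    backtranslate,
    estimate_divergence,
    family_kaks_compare,
    four_dtv,
    fourfold_sites,
    ng86,
    simulate_paleotetraploid,
)
from wgdkit.molevol import (
    SENSE_CODONS,
    STOP_CODONS,
    translate_alignment,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_fourfold(codon_a: str, codon_b: str) -> bool:
    """Direct 64-codon tabulation: shared prefix encodes one amino acid."""
    if codon_a[:2] != codon_b[:2]:
        return False
    prefix = codon_a[:2]
    aas = {str(Seq(prefix + b).translate()) for b in "ACGT"}
    return len(aas) == 1 and "*" not in aas


def oracle_ng86_codon_pair(c1: str, c2: str):
    """Brute-force NG86 for one codon pair: site counts + pathway averaging."""

    def sites(codon):
        aa = str(Seq(codon).translate())
        syn = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1 :]
                if str(Seq(mut).translate()) not in ("*",) and str(
                    Seq(mut).translate()
                ) == aa:
                    syn += 1 / 3
        return syn, 3 - syn

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    pathways = []
    for order in itertools.permutations(diffs):
        steps, current, blocked = [], c1, False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if str(Seq(nxt).translate()) == "*":
                blocked = True
                break
            steps.append(
                str(Seq(nxt).translate()) == str(Seq(current).translate())
            )
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not diffs:
        sd = nd = 0.0
    elif pathways:
        sd = sum(sum(p) for p in pathways) / len(pathways)
        nd = sum(len(p) - sum(p) for p in pathways) / len(pathways)
    else:
        sd = nd = None  # all pathways through stops; fallback case
    return sites(c1), sites(c2), sd, nd


def _aln(codons_a, codons_b):
    return CodonAlignment("x", "y", list(codons_a), list(codons_b))


class TestBacktranslate:
    def test_identical_two_residue_proteins(self):
        aln = backtranslate("MK", "MK", "ATGAAA", "ATGAAG")
        assert len(aln) == 2
        assert aln.codons_a == ["ATG", "AAA"]
        assert aln.codons_b == ["ATG", "AAG"]

    def test_gap_column_becomes_gap_triplet(self):
        aln = backtranslate("MK-", "MKV", "ATGAAA", "ATGAAAGTT")
        assert aln.codons_a[2] == "---"
        assert aln.codons_b[2] == "GTT"

    def test_mismatch_error_names_position(self):
        with pytest.raises(FormatError, match="residue 1"):
            backtranslate("MK", "MK", "ATGCCC", "ATGAAA")  # CCC is P, not K

    def test_round_trip_on_simulated_pairs(self, small_dataset):
        from wgdkit.homology import align_global

        focal = small_dataset.focal
        pairs = list(small_dataset.truth.paralog_pairs)[:10]
        for a, b in pairs:
            prot_a, prot_b = focal.protein(a), focal.protein(b)
            row_a, row_b = align_global(prot_a, prot_b)
            aln = backtranslate(row_a, row_b, focal.cds[a], focal.cds[b], a, b)
            assert translate_alignment(aln) == (row_a, row_b)


class TestFourfoldSites:
    def test_alanine_column_included(self):
        assert fourfold_sites(_aln(["GCT"], ["GCA"])) == [0]

    def test_phenylalanine_column_excluded(self):
        assert fourfold_sites(_aln(["TTT"], ["TTC"])) == []

    def test_site_set_equals_lookup_oracle(self, rng):
        codons = list(SENSE_CODONS)
        for _ in range(30):
            row_a = [codons[i] for i in rng.integers(len(codons), size=30)]
            row_b = [codons[i] for i in rng.integers(len(codons), size=30)]
            aln = _aln(row_a, row_b)
            expected = [
                i for i in range(30) if oracle_fourfold(row_a[i], row_b[i])
            ]
            assert fourfold_sites(aln) == expected


class TestFourDtv:
    def test_identical_sequences_zero(self):
        est = four_dtv(_aln(["GCT", "GGA"], ["GCT", "GGA"]))
        assert est.fourdtv_raw == 0.0
        assert est.fourdtv_corrected == 0.0

    def test_worked_example_two_tv_three_ts_of_ten(self):
        # ten 4D columns: 2 transversion-differing, 3 transition-differing
        row_a = ["GCT"] * 10
        row_b = (
            ["GCA", "GCA"]  # T->A transversions
            + ["GCC", "GCC", "GCC"]  # T->C transitions
            + ["GCT"] * 5
        )
        est = four_dtv(_aln(row_a, row_b))
        assert est.n_4d_sites == 10
        assert est.fourdtv_raw == pytest.approx(0.2)
        assert est.fourdtv_corrected == pytest.approx(-0.5 * math.log(0.6))
        assert est.fourdtv_corrected == pytest.approx(0.2554, abs=5e-4)

    def test_raw_half_is_saturated(self):
        est = four_dtv(_aln(["GCT", "GCT"], ["GCA", "GCT"]))
        assert est.fourdtv_raw == 0.5
        assert est.fourdtv_saturated
        assert math.isnan(est.fourdtv_corrected)

    def test_no_eligible_sites_undefined_not_error(self):
        est = four_dtv(_aln(["TTT"], ["TTC"]))
        assert est.n_4d_sites == 0
        assert math.isnan(est.fourdtv_raw)

    def test_correction_monotone_in_raw(self):
        raws = np.linspace(0.0, 0.49, 50)
        corrected = [-0.5 * math.log(1 - 2 * r) for r in raws]
        assert all(b > a for a, b in zip(corrected, corrected[1:]))
        assert all(c >= r for r, c in zip(raws, corrected))


class TestNg86:
    def test_synonymous_only_changes_give_zero_ka(self):
        est = ng86(_aln(["GCT"] * 10, ["GCA"] + ["GCT"] * 9))
        assert est.ka == 0.0
        assert est.ks > 0.0

    def test_identical_sequences_undefined_ratio(self):
        est = ng86(_aln(["ATG", "GCT"], ["ATG", "GCT"]))
        assert est.ka == 0.0
        assert est.ks == 0.0
        assert math.isnan(est.ka_ks)

    def test_all_sense_codon_pairs_match_pathway_oracle(self):
        """Exact agreement with brute-force enumeration on all 61x61 pairs."""
        from wgdkit.molevol import _codon_site_counts, _pair_differences

        for c1 in SENSE_CODONS:
            (s1, n1), _, _, _ = oracle_ng86_codon_pair(c1, c1)
            assert _codon_site_counts(c1) == pytest.approx((s1, n1))
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                _, _, sd, nd = oracle_ng86_codon_pair(c1, c2)
                got_sd, got_nd = _pair_differences(c1, c2)
                if sd is None:
                    # blocked-pathway fallback: totals must still add up
                    ndiff = sum(1 for i in range(3) if c1[i] != c2[i])
                    assert got_sd + got_nd == pytest.approx(ndiff)
                else:
                    assert got_sd == pytest.approx(sd)
                    assert got_nd == pytest.approx(nd)

    def test_two_position_codon_pair_matches_oracle_through_alignment(self):
        pad = ["AAA"] * 9  # identical context keeps proportions in range
        est = ng86(_aln(["TTT"] + pad, ["GTA"] + pad))
        (sa, na), (sb, nb), sd, nd = oracle_ng86_codon_pair("TTT", "GTA")
        (sp, np_), _, _, _ = oracle_ng86_codon_pair("AAA", "AAA")
        s_sites = (sa + sb) / 2 + 9 * sp
        n_sites = (na + nb) / 2 + 9 * np_
        ps, pn = sd / s_sites, nd / n_sites
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3))
        assert est.ka == pytest.approx(-0.75 * math.log(1 - 4 * pn / 3))


class TestFamilyComparison:
    def test_identical_groups_give_p_one(self):
        ests = []
        labels = {}
        for i in range(6):
            est = estimate_divergence(_aln(["GCT"] * 10, ["GCA"] + ["GCT"] * 9))
            est.id_a, est.id_b, est.ka_ks = f"a{i}", f"b{i}", 0.5
            ests.append(est)
            if i < 3:
                labels[(f"a{i}", f"b{i}")] = "fam"
        report = family_kaks_compare(ests, labels)
        assert report["families"]["fam"]["p"] == pytest.approx(1.0)

    def test_seeded_normal_contrast_is_significant(self):
        rng = np.random.default_rng(1234)
        background = rng.normal(0.45, 0.1, size=200)
        family = rng.normal(0.61, 0.1, size=50)
        t, p = stats.ttest_ind(family, background, equal_var=False)
        assert p < 0.01  # sanity on the constructed contrast
        ests, labels = [], {}
        everything = np.concatenate([background, family])
        for i, v in enumerate(everything):
            est = estimate_divergence(_aln(["GCT"] * 10, ["GCA"] + ["GCT"] * 9))
            est.id_a, est.id_b, est.ka_ks = f"a{i}", f"b{i}", float(v)
            ests.append(est)
            if i >= 200:
                labels[(f"a{i}", f"b{i}")] = "CC-NBS-LRR"
        report = family_kaks_compare(ests, labels)
        fam = report["families"]["CC-NBS-LRR"]
        # the default reference is the genome-wide pool (family included)
        _, p_pool = stats.ttest_ind(family, everything, equal_var=False)
        assert fam["p"] == pytest.approx(p_pool)
        assert fam["p"] < 0.01
        assert report["genome_wide_mean"] == pytest.approx(everything.mean())

    def test_welch_t_matches_hand_formula_on_three_vs_three(self):
        x, y = [0.2, 0.3, 0.4], [0.5, 0.7, 0.9]
        ests, labels = [], {}
        for i, v in enumerate(x + y):
            est = estimate_divergence(_aln(["GCT"], ["GCA"]))
            est.id_a, est.id_b, est.ka_ks = f"a{i}", f"b{i}", v
            ests.append(est)
            if i >= 3:
                labels[(f"a{i}", f"b{i}")] = "fam"
        report = family_kaks_compare(ests, labels)
        mx, my = np.mean(x), np.mean(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        t_hand = (my - mx) / math.sqrt(vx / 3 + vy / 3)
        # reference here is the genome-wide pool (x + y)
        pool = x + y
        vp = np.var(pool, ddof=1)
        t_vs_pool = (my - np.mean(pool)) / math.sqrt(vy / 3 + vp / 6)
        assert report["families"]["fam"]["t"] == pytest.approx(t_vs_pool)
        assert t_hand > 0  # direction sanity


class TestEstimateDivergenceOnSimulation:
    def test_kaks_reflects_simulated_purifying_pressure(self, small_dataset):
        """omega_sim thins nonsynonymous changes, so Ka/Ks lands below 1."""
        from wgdkit.homology import align_global

        focal = small_dataset.focal
        ratios = []
        for a, b in list(small_dataset.truth.paralog_pairs)[:40]:
            row_a, row_b = align_global(focal.protein(a), focal.protein(b))
            aln = backtranslate(row_a, row_b, focal.cds[a], focal.cds[b], a, b)
            est = estimate_divergence(aln)
            if est.ka_ks_defined:
                ratios.append(est.ka_ks)
        assert len(ratios) >= 20
        assert 0.05 < np.mean(ratios) < 0.6
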