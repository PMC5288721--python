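"""Simulator correctness: determinism, bookkeeping, substitution model."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.linalg import expm

from wgdkit import (
    EvolutionParams,
    apply_wgd_and_diverge,
    emit_outgroup,
    emit_synthetic_map,
    expected_corrected_4dtv,
    expected_two_copy_fraction,
    simulate_ancestor,
    simulate_paleotetraploid,
)
from wgdkit.molevol import FOURFOLD_PREFIXES
from wgdkit.synth_genome import _evolve_cds


def k2p_transversion_probability(total_divergence: float, kappa: float) -> float:
    """Oracle: transversion-difference probability from the rate matrix.

    Bases ordered A, G, C, T; transitions A<->G and C<->T at rate kappa*beta,
    transversions at rate beta, scaled so the per-site rate is one expected
    substitution per unit time; the matrix exponential at t=total_divergence
    gives the substitution probabilities.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    q = np.array(
        [
            [0.0, alpha, beta, beta],
            [alpha, 0.0, beta, beta],
            [beta, beta, 0.0, alpha],
            [beta, beta, alpha, 0.0],
        ]
    )
    np.fill_diagonal(q, -q.sum(axis=1))
    p = expm(q * total_divergence)
    # transversions from A are to C and T (columns 2, 3); symmetric for all bases
    return float(p[0, 2] + p[0, 3])


class TestAncestor:
    def test_counts_and_ranks(self):
        params = EvolutionParams(n_chromosomes=2, genes_per_chromosome=50, seed=1)
        ann = simulate_ancestor(params)
        assert len(ann.genes) == 100
        for seq_id in ann.seq_ids():
            assert [g.rank for g in ann.genes_on(seq_id)] == list(range(50))

    def test_same_seed_identical(self):
        params = EvolutionParams(n_chromosomes=1, genes_per_chromosome=20, seed=5)
        a, b = simulate_ancestor(params), simulate_ancestor(params)
        assert a.cds == b.cds
        assert a.chromosomes == b.chromosomes
        assert a.genes == b.genes

    def test_cds_translate_without_internal_stops(self):
        params = EvolutionParams(n_chromosomes=1, genes_per_chromosome=30, seed=2)
        ann = simulate_ancestor(params)
        for gid, cds in ann.cds.items():
            protein = str(Seq(cds).translate())
            assert "*" not in protein, gid
            assert protein.startswith("M")

    def test_gene_sequences_embedded_in_chromosome(self):
        params = EvolutionParams(n_chromosomes=1, genes_per_chromosome=10, seed=4)
        ann = simulate_ancestor(params)
        for g in ann.genes:
            embedded = ann.chromosomes[g.seq_id][g.start - 1 : g.end]
            expected = ann.cds[g.gene_id]
            if g.strand == "-":
                expected = str(Seq(expected).reverse_complement())
            assert embedded == expected


class TestWgdAndDivergence:
    def test_no_loss_doubles_genes_and_pairs_everything(self, lossless_dataset):
        ds = lossless_dataset
        n_anc = len(ds.ancestor.genes)
        assert len(ds.focal.genes) == 2 * n_anc
        assert len(ds.truth.paralog_pairs) == n_anc
        paired = {g for pair in ds.truth.paralog_pairs for g in pair}
        assert len(paired) == 2 * n_anc  # every surviving gene in exactly one pair

    def test_zero_branch_gives_identical_paralogs(self):
        params = EvolutionParams(
            n_chromosomes=1,
            genes_per_chromosome=15,
            wgd_branch_length=0.0,
            loss_probability=0.0,
            seed=9,
        )
        ancestor = simulate_ancestor(params)
        focal, truth = apply_wgd_and_diverge(ancestor, params)
        for a, b in truth.paralog_pairs:
            assert focal.cds[a] == focal.cds[b]

    def test_loss_probability_one_rejected(self):
        with pytest.raises(ValueError):
            EvolutionParams(loss_probability=1.0)

    def test_gene_count_bookkeeping_matches_loss_flags(self, small_dataset):
        truth = small_dataset.truth
        survivors = sum(sum(flags) for flags in truth.loss_flags.values())
        assert len(small_dataset.focal.genes) == survivors

    def test_transversion_proportion_matches_matrix_exponential(self):
        """Pooled 4D sites vs the rate-matrix oracle, within 3 binomial SE."""
        kappa, branch = 2.0, 0.05
        rng = np.random.default_rng(17)
        params = EvolutionParams(n_chromosomes=1, genes_per_chromosome=1, seed=0)
        n_sites = n_tv = 0
        purines = frozenset("AG")
        for _ in range(120):
            ancestor = simulate_ancestor(
                EvolutionParams(
                    n_chromosomes=1,
                    genes_per_chromosome=1,
                    codon_length_min=200,
                    codon_length_max=200,
                    seed=int(rng.integers(2**31)),
                )
            )
            cds = next(iter(ancestor.cds.values()))
            left, _ = _evolve_cds(cds, branch, kappa, params.omega_sim, rng)
            right, _ = _evolve_cds(cds, branch, kappa, params.omega_sim, rng)
            for i in range(0, len(cds), 3):
                ca, cb = left[i : i + 3], right[i : i + 3]
                if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
                    n_sites += 1
                    if ca[2] != cb[2] and (ca[2] in purines) != (cb[2] in purines):
                        n_tv += 1
        assert n_sites >= 10_000
        expected = k2p_transversion_probability(2 * branch, kappa)
        se = math.sqrt(expected * (1 - expected) / n_sites)
        assert abs(n_tv / n_sites - expected) < 3 * se

    def test_realized_divergence_consistent_with_branch_lengths(self, small_dataset):
        truth = small_dataset.truth
        realized = np.array([t.realized for t in truth.paralog_pairs.values()])
        expected = 2 * small_dataset.params.wgd_branch_length
        se = realized.std(ddof=1) / math.sqrt(len(realized))
        assert abs(realized.mean() - expected) < 3 * se

    def test_corrected_4dtv_expectation_closed_form(self):
        """-1/2 ln(1-2v) applied to the matrix-exponential v recovers 2*beta*t."""
        for d, kappa in [(0.146, 2.0), (0.28, 2.0), (0.1, 4.0)]:
            v = k2p_transversion_probability(d, kappa)
            assert -0.5 * math.log(1 - 2 * v) == pytest.approx(
                expected_corrected_4dtv(d, kappa), rel=1e-9
            )


class TestRearrangements:
    def test_inversions_and_translocations_keep_genes_and_ranks_valid(self):
        base = dict(n_chromosomes=2, genes_per_chromosome=40,
                    codon_length_min=10, codon_length_max=12, seed=37)
        plain = simulate_paleotetraploid(EvolutionParams(**base))
        shuffled = simulate_paleotetraploid(
            EvolutionParams(**base, inversion_count=3, translocation_count=2)
        )
        # rearrangement moves genes around but neither creates nor destroys them
        ids = lambda ds: sorted(g.gene_id for g in ds.focal.genes)
        assert ids(shuffled) == ids(plain)
        for seq_id in shuffled.focal.seq_ids():
            on_seq = shuffled.focal.genes_on(seq_id)
            assert [g.rank for g in on_seq] == list(range(len(on_seq)))

    def test_inversion_flips_strands_somewhere(self):
        base = dict(n_chromosomes=1, genes_per_chromosome=40,
                    codon_length_min=10, codon_length_max=12,
                    loss_probability=0.0, seed=41)
        plain = simulate_paleotetraploid(EvolutionParams(**base))
        inverted = simulate_paleotetraploid(
            EvolutionParams(**base, inversion_count=2)
        )
        strands = lambda ds: {g.gene_id: g.strand for g in ds.focal.genes}
        assert strands(plain) != strands(inverted)


class TestOutgroup:
    def test_no_loss_gives_two_homologs_each(self, lossless_dataset):
        truth = lossless_dataset.truth
        per_outgroup = {}
        for o, _f in truth.ortholog_pairs:
            per_outgroup[o] = per_outgroup.get(o, 0) + 1
        assert set(per_outgroup.values()) == {2}
        assert len(per_outgroup) == len(lossless_dataset.ancestor.genes)

    def test_zero_branch_outgroup_identical_to_ancestor(self):
        params = EvolutionParams(
            n_chromosomes=1, genes_per_chromosome=10,
            speciation_branch_length=0.0, seed=8,
        )
        ancestor = simulate_ancestor(params)
        outgroup = emit_outgroup(ancestor, params)
        for g in ancestor.genes:
            assert outgroup.cds[g.gene_id + "o"] == ancestor.cds[g.gene_id]

    def test_two_homolog_fraction_matches_independent_loss_model(self):
        p = 0.3
        params = EvolutionParams(
            n_chromosomes=2,
            genes_per_chromosome=500,
            codon_length_min=10,
            codon_length_max=12,
            wgd_branch_length=0.0,
            speciation_branch_length=0.0,
            loss_probability=p,
            seed=21,
        )
        ds = simulate_paleotetraploid(params)
        with_any = [
            g for g, flags in ds.truth.loss_flags.items() if any(flags)
        ]
        with_two = [g for g in with_any if all(ds.truth.loss_flags[g])]
        frac = len(with_two) / len(with_any)
        expected = expected_two_copy_fraction(p)
        se = math.sqrt(expected * (1 - expected) / len(with_any))
        assert abs(frac - expected) < 3 * se


class TestSyntheticMap:
    def test_zero_jitter_cm_increases_with_position(self, lossless_dataset):
        markers, _, truth = emit_synthetic_map(lossless_dataset.focal, 8, rng=1)
        by_lg = {}
        for m in markers:
            by_lg.setdefault(m.linkage_group, []).append(m)
        for group in by_lg.values():
            group.sort(key=lambda m: truth.markers[m.marker_id][1])
            positions = [m.position for m in group]
            assert positions == sorted(positions)
            assert len(set(positions)) == len(positions)

    def test_single_fragment_is_identity_ordering(self, lossless_dataset):
        _, scaffolds, truth = emit_synthetic_map(
            lossless_dataset.focal, 6, rng=2, fragments_per_chromosome=1
        )
        assert len(scaffolds) == len(lossless_dataset.focal.chromosomes)
        assert all(order == 0 for _, order, _ in truth.scaffolds.values())

    def test_flanks_occur_exactly_once(self, lossless_dataset):
        markers, scaffolds, _ = emit_synthetic_map(lossless_dataset.focal, 6, rng=3)
        from wgdkit.synth_genome import _revcomp

        for m in markers[:20]:
            occurrences = 0
            for seq in scaffolds.values():
                occurrences += seq.count(m.flank) + seq.count(_revcomp(m.flank))
            assert occurrences == 1, m.marker_id

    def test_fewer_than_two_markers_warns(self, lossless_dataset):
        import warnings as w

        with w.catch_warnings(record=True) as caught:
            w.simplefilter("always")
            emit_synthetic_map(lossless_dataset.focal, 1, rng=4)
        assert any("orientation untestable" in str(c.message) for c in caught)

    def test_determinism_of_full_dataset(self):
        params = EvolutionParams(n_chromosomes=1, genes_per_chromosome=25, seed=13)
        a, b = simulate_paleotetraploid(params), simulate_paleotetraploid(params)
        assert a.focal.cds == b.focal.cds
        assert a.truth.paralog_pairs == b.truth.paralog_pairs
        assert a.truth.ortholog_pairs == b.truth.ortholog_pairs
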