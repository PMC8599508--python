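import random

import numpy as np
import pytest

from egtscan.genetrees import parse_newick
from egtscan.matrixtools import (
    GeneAlignment,
    MatrixError,
    Supermatrix,
    chi2_site_scores,
    chi2_total,
    concatenate,
    ef2_signature,
    filter_genes_by_focal_count,
    fitch_site_rates,
    merge_otus,
    read_fasta_alignment,
    read_site_rates,
    remove_fastest_sites,
    trim_heterogeneous_sites,
    write_fasta_alignment,
)
from .oracles import chi2_scores_oracle, fitch_steps_oracle

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(rng, gene_id, taxa, length, gap_p=0.1):
    rows = {}
    for t in taxa:
        rows[t] = "".join(
            "-" if rng.random() < gap_p else rng.choice(AAS) for _ in range(length)
        )
    return GeneAlignment(gene_id=gene_id, rows=rows)


class TestGeneAlignment:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(MatrixError):
            GeneAlignment("g", {"a": "AAA", "b": "AA"})

    def test_fasta_roundtrip(self, tmp_path):
        aln = GeneAlignment("g1", {"t1": "AC-DE", "t2": "ACXDE"})
        path = tmp_path / "g1.fasta"
        write_fasta_alignment(aln, path)
        back = read_fasta_alignment(path)
        assert back.rows == aln.rows
        assert back.gene_id == "g1"


class TestMergeOtus:
    def test_occupancy_increases(self):
        g1 = GeneAlignment("g1", {"m1": "AAAA", "x": "CCCC"})
        g2 = GeneAlignment("g2", {"m2": "DDDD", "x": "CCCC"})
        merged = merge_otus([g1, g2], {"OTU1": ["m1", "m2"]})
        assert "OTU1" in merged[0].rows and "OTU1" in merged[1].rows
        assert merged[0].rows["OTU1"] == "AAAA"
        assert merged[1].rows["OTU1"] == "DDDD"
        assert "m1" not in merged[0].rows

    def test_fewest_missing_wins(self):
        g = GeneAlignment("g", {"m1": "A---", "m2": "AAX-"})
        merged = merge_otus([g], {"O": ["m1", "m2"]})
        # m1 has 3 missing, m2 has 2 -> m2 wins
        assert merged[0].rows["O"] == "AAX-"

    def test_tie_broken_by_member_order(self):
        g = GeneAlignment("g", {"m1": "AA--", "m2": "CC--"})
        merged = merge_otus([g], {"O": ["m1", "m2"]})
        assert merged[0].rows["O"] == "AA--"

    def test_absent_only_if_all_members_absent(self):
        g = GeneAlignment("g", {"other": "AAAA"})
        merged = merge_otus([g], {"O": ["m1", "m2"]})
        assert "O" not in merged[0].rows

    def test_collision_error(self):
        g = GeneAlignment("g", {"O": "AAAA", "m1": "CCCC"})
        with pytest.raises(MatrixError):
            merge_otus([g], {"O": ["m1"]})

    def test_occupancy_never_decreases(self):
        rng = random.Random(0)
        genes = [
            random_alignment(rng, f"g{i}", ["m1", "m2", "m3", "x"], 30, gap_p=0.4)
            for i in range(5)
        ]
        merged = merge_otus(genes, {"O": ["m1", "m2", "m3"]})
        for orig, m in zip(genes, merged):
            best = min(orig.missing_count(t) for t in ("m1", "m2", "m3"))
            assert m.missing_count("O") == best


class TestFilterGenes:
    def test_counts(self, tmap):
        taxa_sets = [
            [],
            ["Focal_A01"],
            ["Focal_A01", "Focal_A02"],
            ["Focal_A01", "Focal_A02", "Focal_A03"],
        ]
        genes = []
        for i, focals in enumerate(taxa_sets):
            rows = {"Photo1": "AAAA"}
            rows.update({t: "CCCC" for t in focals})
            genes.append(GeneAlignment(f"g{i}", rows))
        kept = filter_genes_by_focal_count(genes, tmap, "Focal", 2)
        assert [g.gene_id for g in kept] == ["g2", "g3"]

    def test_min_zero_is_identity(self, tmap):
        genes = [GeneAlignment("g", {"Photo1": "AA"})]
        assert filter_genes_by_focal_count(genes, tmap, "Focal", 0) == genes

    def test_all_gap_focal_row_not_counted(self, tmap):
        g = GeneAlignment("g", {"Focal_A01": "----", "Focal_A02": "AAAA",
                                "Photo1": "CCCC"})
        assert filter_genes_by_focal_count([g], tmap, "Focal", 2) == []
        assert filter_genes_by_focal_count([g], tmap, "Focal", 1) == [g]


class TestConcatenate:
    def test_partitions(self):
        genes = [
            GeneAlignment("g1", {"a": "A" * 10}),
            GeneAlignment("g2", {"a": "C" * 20}),
            GeneAlignment("g3", {"a": "D" * 30}),
        ]
        sm = concatenate(genes)
        assert sm.length == 60
        assert [(p.start, p.end) for p in sm.partitions] == [(1, 10), (11, 30), (31, 60)]

    def test_missing_block_gap_filled(self):
        genes = [
            GeneAlignment("g1", {"a": "AA", "b": "CC"}),
            GeneAlignment("g2", {"a": "DD"}),
        ]
        sm = concatenate(genes)
        assert sm.rows["b"] == "CC--"

    def test_empty_error(self):
        with pytest.raises(MatrixError):
            concatenate([])

    def test_duplicate_gene_error(self):
        g = GeneAlignment("g", {"a": "AA"})
        with pytest.raises(MatrixError):
            concatenate([g, g])

    def test_roundtrip_slice(self):
        rng = random.Random(1)
        taxa = [f"t{i}" for i in range(6)]
        genes = []
        for i in range(4):
            present = rng.sample(taxa, rng.randint(2, 6))
            L = rng.randint(5, 15)
            genes.append(
                GeneAlignment(
                    f"g{i}",
                    {t: "".join(rng.choice(AAS) for _ in range(L))
                     for t in present},
                )
            )
        sm = concatenate(genes)
        for gene in genes:
            back = sm.slice_partition(gene.gene_id)
            assert back.rows == gene.rows


class TestFitch:
    def test_single_change(self):
        t = parse_newick("((A,B),(C,D));")
        sm = Supermatrix(rows={"A": "K", "B": "K", "C": "R", "D": "R"})
        assert fitch_site_rates(sm, t).tolist() == [1.0]

    def test_constant_column(self):
        t = parse_newick("((A,B),(C,D));")
        sm = Supermatrix(rows={"A": "K", "B": "K", "C": "K", "D": "K"})
        assert fitch_site_rates(sm, t).tolist() == [0.0]

    def test_two_changes(self):
        t = parse_newick("((A,B),(C,D));")
        sm = Supermatrix(rows={"A": "K", "B": "R", "C": "K", "D": "R"})
        assert fitch_site_rates(sm, t).tolist() == [2.0]

    def test_gap_excluded(self):
        t = parse_newick("((A,B),(C,D));")
        sm = Supermatrix(rows={"A": "K", "B": "-", "C": "R", "D": "X"})
        assert fitch_site_rates(sm, t).tolist() == [1.0]

    def test_all_gap_column(self):
        t = parse_newick("((A,B),(C,D));")
        sm = Supermatrix(rows={"A": "-", "B": "-", "C": "-", "D": "-"})
        assert fitch_site_rates(sm, t).tolist() == [0.0]

    def test_strict_taxon_mismatch(self):
        t = parse_newick("((A,B),(C,E));")
        sm = Supermatrix(rows={"A": "K", "B": "K", "C": "K", "D": "K"})
        with pytest.raises(MatrixError):
            fitch_site_rates(sm, t, strict=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        from .oracles import random_binary_newick

        n = rng.randint(4, 7)
        t = parse_newick(random_binary_newick(n, seed, prefix="T"))
        taxa = sorted(t.leaves)
        rows = {
            x: "".join(rng.choice("KRDE-") for _ in range(8)) for x in taxa
        }
        sm = Supermatrix(rows=rows)
        rates = fitch_site_rates(sm, t)
        for site in range(8):
            column = {x: rows[x][site] for x in taxa}
            assert rates[site] == fitch_steps_oracle(t, column), (site, column)


class TestRemoveFastestSites:
    def test_sort_order_small(self):
        sm = Supermatrix(rows={"a": "KRD", "b": "KRD"})
        rates = np.array([3.0, 1.0, 2.0])
        out = remove_fastest_sites(sm, rates, step=1, max_removed=2)
        assert [m.length for m in out] == [2, 1]
        assert out[0].rows["a"] == "RD"  # site 1 (rate 3) removed
        assert out[1].rows["a"] == "R"  # sites 1 and 3 removed

    def test_arithmetic(self):
        rng = random.Random(2)
        rows = {"a": "".join(rng.choice(AAS) for _ in range(12000)),
                "b": "".join(rng.choice(AAS) for _ in range(12000))}
        sm = Supermatrix(rows=rows)
        rates = np.array([rng.random() for _ in range(12000)])
        out = remove_fastest_sites(sm, rates, step=5000, max_removed=10000)
        assert [m.length for m in out] == [7000, 2000]

    def test_nested_removal(self):
        rng = random.Random(3)
        L = 50
        sm = Supermatrix(rows={"a": "A" * L, "b": "C" * L})
        rates = np.array([rng.random() for _ in range(L)])
        outs = remove_fastest_sites(sm, rates, step=10, max_removed=40)
        # removed sets nested == full-sort oracle prefix sets
        oracle = sorted(range(L), key=lambda i: (-rates[i], i))
        for k, m in enumerate(outs, 1):
            assert m.length == L - 10 * k

    def test_tie_break_by_index(self):
        sm = Supermatrix(rows={"a": "KRDE", "b": "KRDE"})
        rates = np.array([1.0, 1.0, 1.0, 1.0])
        out = remove_fastest_sites(sm, rates, step=2, max_removed=2)
        assert out[0].rows["a"] == "DE"  # first two indices removed

    def test_cannot_empty_matrix(self):
        sm = Supermatrix(rows={"a": "KR", "b": "KR"})
        with pytest.raises(MatrixError):
            remove_fastest_sites(sm, np.array([1.0, 2.0]), step=1, max_removed=2)

    def test_partitions_respanned(self):
        from egtscan.matrixtools import Partition

        sm = Supermatrix(
            rows={"a": "KKRR", "b": "KKRR"},
            partitions=[Partition("g1", 1, 2), Partition("g2", 3, 4)],
        )
        rates = np.array([5.0, 1.0, 6.0, 2.0])
        out = remove_fastest_sites(sm, rates, step=2, max_removed=2)
        assert [(p.gene_id, p.start, p.end) for p in out[0].partitions] == [
            ("g1", 1, 1),
            ("g2", 2, 2),
        ]

    def test_partition_dropped_when_empty(self):
        from egtscan.matrixtools import Partition

        sm = Supermatrix(
            rows={"a": "KKRR", "b": "KKRR"},
            partitions=[Partition("g1", 1, 2), Partition("g2", 3, 4)],
        )
        rates = np.array([5.0, 6.0, 1.0, 2.0])
        out = remove_fastest_sites(sm, rates, step=2, max_removed=2)
        assert [p.gene_id for p in out[0].partitions] == ["g2"]


class TestChi2:
    def test_hand_example(self):
        sm = Supermatrix(rows={"t1": "AA", "t2": "AC"})
        assert chi2_total(sm) == pytest.approx(4 / 3)
        scores = chi2_site_scores(sm)
        assert scores[1] == pytest.approx(4 / 3)
        assert scores[0] == pytest.approx(-2 / 3)

    def test_identical_rows_score_zero(self):
        sm = Supermatrix(rows={"t1": "ACDEF", "t2": "ACDEF", "t3": "ACDEF"})
        assert chi2_site_scores(sm) == pytest.approx(np.zeros(5))

    def test_matches_full_recomputation_oracle(self):
        rng = random.Random(4)
        for trial in range(10):
            n_taxa = rng.randint(3, 8)
            L = rng.randint(4, 30)
            rows = {
                f"t{i}": "".join(
                    "-" if rng.random() < 0.1 else rng.choice(AAS) for _ in range(L)
                )
                for i in range(n_taxa)
            }
            sm = Supermatrix(rows=rows)
            got = chi2_site_scores(sm)
            expected = chi2_scores_oracle(rows)
            assert got == pytest.approx(expected, abs=1e-9), f"trial {trial}"

    def test_duplicated_columns_preserve_ranking(self):
        # duplicating every column must not change which sites look
        # heterogeneous; near-tied sites can legitimately swap because the
        # single-site removal score is nonlinear in the global frequencies,
        # so this asserts rank agreement rather than exact order
        from scipy.stats import spearmanr

        rng = random.Random(5)
        L = 12
        rows = {f"t{i}": "".join(rng.choice("ACDE") for _ in range(L))
                for i in range(5)}
        sm = Supermatrix(rows=rows)
        s1 = chi2_site_scores(sm)
        doubled = Supermatrix(rows={t: r + r for t, r in rows.items()})
        s2 = chi2_site_scores(doubled)[:L]
        rho = spearmanr(s1, s2).statistic
        assert rho > 0.95
        top = 3
        assert set(np.argsort(-s1)[:top]) == set(np.argsort(-s2)[:top])

    def test_all_gap_error(self):
        sm = Supermatrix(rows={"t1": "--", "t2": "--"})
        with pytest.raises(MatrixError):
            chi2_total(sm)


class TestTrim:
    def test_half_of_four(self):
        rng = random.Random(6)
        rows = {f"t{i}": "".join(rng.choice(AAS) for _ in range(4)) for i in range(4)}
        sm = Supermatrix(rows=rows)
        assert trim_heterogeneous_sites(sm, 0.5).length == 2

    def test_ceiling_rule(self):
        rng = random.Random(7)
        rows = {f"t{i}": "".join(rng.choice(AAS) for _ in range(317))
                for i in range(4)}
        sm = Supermatrix(rows=rows)
        assert trim_heterogeneous_sites(sm, 0.25).length == 317 - 80

    def test_tie_break_removes_first_indices(self):
        sm = Supermatrix(rows={"t1": "AAAA", "t2": "AAAA"})  # all scores 0
        out = trim_heterogeneous_sites(sm, 0.5)
        assert out.length == 2

    def test_fraction_range(self):
        sm = Supermatrix(rows={"t1": "AC", "t2": "CA"})
        with pytest.raises(MatrixError):
            trim_heterogeneous_sites(sm, 1.0)


class TestSignature:
    def test_derived(self):
        g = GeneAlignment("ef2", {"t": "KSAR"})
        assert ef2_signature(g, (2, 3))["t"] == "derived"

    def test_ancestral(self):
        g = GeneAlignment("ef2", {"t": "KGSR"})
        assert ef2_signature(g, (2, 3))["t"] == "ancestral"

    def test_missing(self):
        g = GeneAlignment("ef2", {"t": "KG-R"})
        assert ef2_signature(g, (2, 3))["t"] == "missing"

    def test_other(self):
        g = GeneAlignment("ef2", {"t": "KTTR"})
        assert ef2_signature(g, (2, 3))["t"] == "other"

    def test_out_of_range(self):
        g = GeneAlignment("ef2", {"t": "KG"})
        with pytest.raises(MatrixError):
            ef2_signature(g, (2, 3))


class TestRateTable:
    def test_read_write_roundtrip(self, tmp_path):
        from egtscan.matrixtools import write_site_rates

        rates = np.array([0.5, 2.0, 1.25])
        path = tmp_path / "rates.tsv"
        write_site_rates(rates, path)
        assert read_site_rates(path).tolist() == rates.tolist()

    def test_comment_header(self, tmp_path):
        path = tmp_path / "rates.tsv"
        path.write_text("# comment\nsite rate\n1 0.5\n2 1.5\n")
        assert read_site_rates(path).tolist() == [0.5, 1.5]


class TestEnrichment:
    def test_planted_bias_recovered(self):
        from egtscan.simulate import simulate_alignment

        sim = simulate_alignment(
            n_taxa=30, n_sites=300, gamma_shape=1.0, biased_taxa=10,
            biased_sites=0.10, bias_strength=1.0, seed=11,
        )
        sm = Supermatrix(rows=sim.alignment.rows)
        scores = chi2_site_scores(sm)
        k = len(sim.biased_sites)
        top = set(np.argsort(-scores, kind="stable")[:k].tolist())
        recall = len(top & set(sim.biased_sites.tolist())) / k
        assert recall >= 0.9
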