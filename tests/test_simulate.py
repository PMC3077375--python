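"""Synthetic-data generator: category realization, determinism, copy proportionality."""

import numpy as np
import pandas as pd
import pytest

from hybridtrace.simulate import (
    CATEGORIES,
    HET_BOTH,
    HET_ONE_DONOR1,
    HET_ONE_DONOR2,
    HOM_HOM_DIFF,
    NON_DISCRIMINATING,
    SimulationConfig,
    build_haplotypes,
    coverage_for_depth,
    generate_donor_genomes,
    generate_expression_profiles,
    simulate_hybrid_reads,
)


def table1_like_config(**kwargs):
    # 11 heterozygous-in-one-donor sites + 1 non-discriminating across 8 genes
    defaults = dict(n_genes=8, transcript_length=300, seed=5)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateDonorGenomes:
    def test_realizes_requested_category_counts(self):
        cfg = table1_like_config()
        ref, table = generate_donor_genomes(cfg)
        assert len(table) == 12
        counts = table["truth_category"].value_counts().to_dict()
        assert counts.get(HET_ONE_DONOR1, 0) == 7
        assert counts.get(HET_ONE_DONOR2, 0) == 4
        assert counts.get(NON_DISCRIMINATING, 0) == 1
        assert counts.get(HOM_HOM_DIFF, 0) == 0

    def test_genotypes_realize_their_category(self):
        cfg = SimulationConfig(
            n_genes=10, transcript_length=200,
            snp_counts={c: 8 for c in CATEGORIES}, seed=9,
        )
        _, table = generate_donor_genomes(cfg)
        for _, r in table.iterrows():
            g1, g2 = sorted(r["donor1_genotype"]), sorted(r["donor2_genotype"])
            cat = r["truth_category"]
            if cat == HOM_HOM_DIFF:
                assert g1[0] == g1[1] and g2[0] == g2[1] and g1 != g2
            elif cat == HET_ONE_DONOR1:
                assert g1[0] != g1[1] and g2[0] == g2[1] and g2[0] in g1
            elif cat == HET_ONE_DONOR2:
                assert g2[0] != g2[1] and g1[0] == g1[1] and g1[0] in g2
            elif cat == HET_BOTH:
                assert g1 == g2 and g1[0] != g1[1]
            else:
                # identical homozygous; may be homozygous-alt (visible in List B)
                assert g1 == g2 and g1[0] == g1[1]
            if cat != NON_DISCRIMINATING:
                # reference base is one of the donor alleles at biallelic sites
                assert r["ref_allele"] in set(g1) | set(g2)

    def test_positions_one_based_and_unique_per_gene(self):
        _, table = generate_donor_genomes(table1_like_config())
        assert (table["position"] >= 1).all()
        assert (table["position"] <= 300).all()
        assert not table.duplicated(["chromosome", "position"]).any()

    def test_non_snp_positions_identical_across_haplotypes(self):
        cfg = table1_like_config()
        ref, table = generate_donor_genomes(cfg)
        haps = build_haplotypes(ref, table, copies_per_donor=2)
        snp_pos = {
            (c, p) for c, p in zip(table["chromosome"], table["position"])
        }
        for gene, seq in ref.items():
            for copy_seqs in haps.values():
                h = copy_seqs[gene]
                for i, (a, b) in enumerate(zip(seq, h)):
                    if (gene, i + 1) not in snp_pos:
                        assert a == b

    def test_zero_counts_give_identical_donors(self):
        cfg = SimulationConfig(n_genes=4, transcript_length=100,
                               snp_counts={}, seed=1)
        _, table = generate_donor_genomes(cfg)
        assert table.empty

    def test_determinism_and_seed_sensitivity(self):
        cfg = table1_like_config(seed=42)
        ref1, t1 = generate_donor_genomes(cfg)
        ref2, t2 = generate_donor_genomes(table1_like_config(seed=42))
        assert ref1 == ref2
        pd.testing.assert_frame_equal(t1, t2)
        ref3, t3 = generate_donor_genomes(table1_like_config(seed=43))
        assert not t1.equals(t3)

    def test_oversized_request_raises(self):
        cfg = SimulationConfig(n_genes=1, transcript_length=10,
                               snp_counts={HOM_HOM_DIFF: 11})
        with pytest.raises(ValueError):
            generate_donor_genomes(cfg)

    @pytest.mark.parametrize(
        "field,value",
        [("error_rate", 1.0), ("error_rate", -0.1), ("coverage", 0.0),
         ("read_length", 0), ("ploidy_model", "hexaploid")],
    )
    def test_config_validation(self, field, value):
        cfg = table1_like_config()
        setattr(cfg, field, value)
        with pytest.raises(ValueError):
            cfg.validate()


class TestExpressionProfiles:
    def test_fold_change_exact_ratio(self):
        cfg = table1_like_config()
        ref, _ = generate_donor_genomes(cfg)
        genes = list(ref)
        cfg.fold_change_spec = {genes[0]: 2.37, genes[1]: -3.82}
        expr = generate_expression_profiles(ref, cfg)
        assert expr.loc[genes[0], "hFL"] / expr.loc[genes[0], "HEF"] == pytest.approx(2 ** 2.37)
        assert expr.loc[genes[1], "hFL"] / expr.loc[genes[1], "HEF"] == pytest.approx(2 ** -3.82)
        assert (expr >= 0).all().all()

    def test_empty_spec_no_large_fold_changes(self):
        cfg = table1_like_config()
        ref, _ = generate_donor_genomes(cfg)
        expr = generate_expression_profiles(ref, cfg)
        lfc = np.log2(expr["hFL"] / expr["HEF"])
        assert (lfc.abs() < 2).all()  # baseline noise never reaches the 4-fold mark

    def test_unknown_gene_raises(self):
        cfg = table1_like_config()
        ref, _ = generate_donor_genomes(cfg)
        cfg.fold_change_spec = {"NOSUCHGENE": 2.0}
        with pytest.raises(ValueError):
            generate_expression_profiles(ref, cfg)


class TestSimulateReads:
    def test_truth_table_complete_and_conserved(self, sim_small):
        rs = sim_small.readset
        assert len(rs.truth) == len(rs.reads)
        assert set(rs.truth["read_id"]) == {r.id for r in rs.reads}
        by_donor = rs.truth["origin_donor"].value_counts()
        assert by_donor.sum() == len(rs.reads)
        assert set(by_donor.index) <= {"donor1", "donor2"}

    def test_error_free_reads_are_haplotype_substrings(self, sim_errorfree):
        ns = sim_errorfree
        haps = build_haplotypes(ns.reference, ns.genotypes, 2)
        truth = ns.readset.truth.set_index("read_id")
        for read in ns.readset.reads[::17]:
            row = truth.loc[read.id]
            copy = int(row["origin_copy_index"])
            donor = row["origin_donor"]
            hap = haps[(donor, copy % 2)][row["origin_transcript"]]
            off = int(row["origin_offset"])
            assert read.sequence == hap[off : off + len(read.sequence)]

    def test_copy_proportionality_at_snp_sites(self):
        # error 0, >= 1e4 reads: per-allele fractions converge to copy fractions
        cfg = SimulationConfig(
            n_genes=2, transcript_length=300,
            snp_counts={HOM_HOM_DIFF: 2, HET_ONE_DONOR1: 2},
            coverage=1300, error_rate=0.0, seed=13,
        )
        ref, gt = generate_donor_genomes(cfg)
        expr = generate_expression_profiles(ref, cfg)
        rs = simulate_hybrid_reads(ref, gt, expr, cfg)
        assert len(rs) >= 10_000
        haps = build_haplotypes(ref, gt, 2)
        truth = rs.truth
        for _, site in gt.iterrows():
            gene, pos = site["chromosome"], int(site["position"])
            covering = truth[
                (truth["origin_transcript"] == gene)
                & (truth["origin_offset"] < pos)
                & (truth["origin_offset"] >= pos - cfg.read_length)
            ]
            n = len(covering)
            alleles = [
                haps[(d, c % 2)][gene][pos - 1]
                for d, c in zip(covering["origin_donor"], covering["origin_copy_index"])
            ]
            counts = pd.Series(alleles).value_counts()
            copy_alleles = [
                haps[(d, c)][gene][pos - 1] for d in ("donor1", "donor2") for c in (0, 1)
            ]
            for allele in set(copy_alleles):
                expected = copy_alleles.count(allele) / 4
                se = np.sqrt(expected * (1 - expected) / n)
                assert abs(counts.get(allele, 0) / n - expected) < 4 * se

    def test_determinism(self):
        cfg = table1_like_config(coverage=20.0)
        ref, gt = generate_donor_genomes(cfg)
        expr = generate_expression_profiles(ref, cfg)
        r1 = simulate_hybrid_reads(ref, gt, expr, cfg)
        r2 = simulate_hybrid_reads(ref, gt, expr, cfg)
        assert [x.sequence for x in r1.reads] == [x.sequence for x in r2.reads]
        pd.testing.assert_frame_equal(r1.truth, r2.truth)

    def test_anchor_contamination(self):
        cfg = table1_like_config(coverage=30.0, anchor_contamination_rate=0.3)
        ref, gt = generate_donor_genomes(cfg)
        expr = generate_expression_profiles(ref, cfg)
        rs = simulate_hybrid_reads(ref, gt, expr, cfg)
        flagged = rs.truth.set_index("read_id")["has_anchor"]
        n_anchor = int(flagged.sum())
        assert 0 < n_anchor < len(rs.reads)
        from hybridtrace.readprep import UP1, UP2

        for read in rs.reads:
            if flagged[read.id]:
                assert read.sequence.startswith(UP1.sequence[: len(read.sequence)]) or \
                    read.sequence.startswith(UP2.sequence[: len(read.sequence)])

    def test_octaploid_keeps_copy_balance(self):
        cfg = table1_like_config(coverage=40.0, ploidy_model="octaploid")
        ref, gt = generate_donor_genomes(cfg)
        expr = generate_expression_profiles(ref, cfg)
        rs = simulate_hybrid_reads(ref, gt, expr, cfg)
        frac = (rs.truth["origin_donor"] == "donor1").mean()
        assert abs(frac - 0.5) < 0.05
        assert rs.truth["origin_copy_index"].nunique() == 8

    def test_fastq_roundtrip(self, tmp_path, sim_errorfree):
        rs = sim_errorfree.readset
        path = tmp_path / "reads.fastq"
        rs.write_fastq(path)
        from hybridtrace.simulate import ReadSet

        back = ReadSet.read_fastq(path, truth=rs.truth)
        assert [r.sequence for r in back.reads] == [r.sequence for r in rs.reads]


def test_coverage_for_depth_roundtrip(sim_small):
    # realized mean depth at SNP sites should be near the targeted 60x
    depths = [
        sim_small.pile.depth(c, p)
        for c, p in zip(sim_small.genotypes["chromosome"], sim_small.genotypes["position"])
    ]
    assert 45 < np.mean(depths) < 75
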