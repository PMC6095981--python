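"""Unique-BCR statistics: frequencies, CLL partition, overlap
coefficients, conditional switch probabilities, gene profiles and
cohort tests."""

import numpy as np
import pandas as pd
import pytest

from bcrnet.network import build_network
from bcrnet.stats import (UniqueBCRTable, anova_one_way, anova_two_way,
                          ighv_isotype_profiles, isotype_frequencies,
                          overlap_coefficients, partition_cll,
                          sample_summaries, switch_probabilities,
                          wilcoxon_rank_sum)


def _airr(rows):
    """rows: (sequence, c_call, duplicate_count, v_call, j_call,
    junction_aa, n_mut_total)"""
    return pd.DataFrame([{
        "sequence": s, "c_call": c, "duplicate_count": d, "v_call": v,
        "j_call": j, "junction_aa": aa, "cdr3_length": len(aa) if aa else 0,
        "n_mut_total": m, "n_mut_silent": 0, "n_mut_nonsilent": m,
        "v_seq_length": len(s), "sample_id": "s1",
    } for s, c, d, v, j, aa, m in rows])


class TestIsotypeFrequencies:
    def test_all_igm_gives_100(self):
        t = UniqueBCRTable.from_airr(_airr(
            [("AAAA", "IGHM", 1, "V1", "J1", "X", 0),
             ("CCCC", "IGHM", 2, "V1", "J1", "Y", 0)]))
        f = isotype_frequencies(t)
        assert f["IGHM"] == 100.0 and len(f) == 1

    def test_presence_event_denominator(self):
        # one IgM-only + one IgM+IgG1 sequence: 3 presence events
        t = UniqueBCRTable.from_airr(_airr(
            [("AAAA", "IGHM", 1, "V1", "J1", "X", 0),
             ("CCCC", "IGHM", 1, "V1", "J1", "Y", 0),
             ("CCCC", "IGHG1", 1, "V1", "J1", "Y", 0)]))
        f = isotype_frequencies(t)
        assert f["IGHM"] == pytest.approx(100 * 2 / 3)
        assert f["IGHG1"] == pytest.approx(100 * 1 / 3)
        assert f.sum() == pytest.approx(100.0)

    def test_empty_table_flagged(self):
        t = UniqueBCRTable(unique=pd.DataFrame(), presence=pd.DataFrame())
        with pytest.raises(ValueError):
            isotype_frequencies(t)


class TestSampleSummaries:
    def test_single_record(self):
        t = UniqueBCRTable.from_airr(_airr(
            [("AAAA", "IGHM", 1, "V1", "J1", "WWWWWWWWWWWWWWW", 3)]))
        s = sample_summaries(t, grouping=None)
        assert s.loc["IGHM", "mean_cdr3_length"] == 15
        assert s.loc["IGHM", "median_mut_nonsilent"] == 3

    def test_median_of_symmetric_counts(self):
        rows = [(f"AAA{b}", "IGHM", 1, "V1", "J1", "X", m)
                for b, m in zip("CGT", (0, 2, 4))]
        t = UniqueBCRTable.from_airr(_airr(rows))
        s = sample_summaries(t, grouping=None)
        assert s.loc["IGHM", "median_mut_nonsilent"] == 2


class TestPartitionCLL:
    def _network(self):
        # dominant cluster: two linked sequences, 80 reads
        rows = [
            ("AAAAAAA", "IGHM", 60, "V1", "J1", "CLL", 0),
            ("AAAAAAT", "IGHM", 20, "V1", "J1", "CLL", 1),
            # same CDR3, different cluster -> rule (2), malignant
            ("CCCCCCC", "IGHG1", 2, "V2", "J1", "CLL", 0),
            # same V-J only -> rule (3), excluded from both repertoires
            ("GGGGGGG", "IGHM", 2, "V1", "J1", "OTHER", 0),
            # unrelated -> non-malignant
            ("TTTTTTT", "IGHA1", 2, "V3", "J2", "DIFF", 0),
        ]
        return build_network(_airr(rows))

    def test_three_rule_partition(self):
        part = partition_cll(self._network())
        assert part.malignant == {"AAAAAAA", "AAAAAAT", "CCCCCCC"}
        assert part.excluded_vj_only == {"GGGGGGG"}
        assert part.non_malignant == {"TTTTTTT"}

    def test_partition_is_exact_on_degenerate_input(self):
        # healthy-style data, CLL mode on: still a well-formed partition
        rows = [(f"AAAA{b}", "IGHM", 1, f"V{i}", "J1", f"X{i}", 0)
                for i, b in enumerate("ACGT")]
        net = build_network(_airr(rows))
        part = partition_cll(net)   # check() runs internally
        total = (len(part.malignant) + len(part.non_malignant)
                 + len(part.excluded_vj_only))
        assert total == 4


class TestOverlap:
    def test_only_exactly_two_isotype_sequences_count(self):
        rows = [
            ("AAAA", "IGHM", 10, "V1", "J1", "X", 0),
            ("AAAA", "IGHA1", 10, "V1", "J1", "X", 0),   # u1: {IgM, IgA1}
            ("CCCC", "IGHM", 10, "V1", "J1", "Y", 0),    # u2: {IgM}
            ("GGGG", "IGHM", 10, "V1", "J1", "Z", 0),    # u3: 3 classes
            ("GGGG", "IGHA1", 10, "V1", "J1", "Z", 0),
            ("GGGG", "IGHG1", 10, "V1", "J1", "Z", 0),
        ]
        t = UniqueBCRTable.from_airr(_airr(rows))
        om = overlap_coefficients(t, depth=8000, n_subsamples=5, seed=0)
        assert not om.subsampled          # < depth reads: one full pass
        assert om.pair_means == {("IgA1/2", "IgD/M"): 1.0}
        m = om.matrix()
        assert m.loc["IgD/M", "IgA1/2"] == 1.0
        assert (m.to_numpy() == m.to_numpy().T).all()

    def test_disjoint_isotypes_give_zero_matrix(self):
        rows = [("AAAA", "IGHM", 5, "V1", "J1", "X", 0),
                ("CCCC", "IGHG1", 5, "V1", "J1", "Y", 0)]
        t = UniqueBCRTable.from_airr(_airr(rows))
        om = overlap_coefficients(t, depth=8000, n_subsamples=5, seed=0)
        assert om.pair_means == {}
        assert om.matrix().to_numpy().sum() == 0

    def test_igm_igd_merged_before_counting(self):
        rows = [("AAAA", "IGHM", 5, "V1", "J1", "X", 0),
                ("AAAA", "IGHD", 5, "V1", "J1", "X", 0)]
        t = UniqueBCRTable.from_airr(_airr(rows))
        om = overlap_coefficients(t, depth=8000, n_subsamples=5, seed=0)
        assert om.pair_means == {}  # IgM+IgD is one class, not a pair

    def test_subsample_normalization_sums_to_one(self, germline):
        from bcrnet.annotate import annotate_cells
        from bcrnet.simulate import SimConfig, simulate_repertoire
        cfg = SimConfig(n_clones=400, clone_size_p=0.3, shm_rate=0.0,
                        founder_switch_probs=0.25, plasmablast_prob=0.0,
                        rna_copies={"naive": 3, "memory": 6, "plasmablast": 6})
        cells, _ = simulate_repertoire(germline, cfg, seed=31)
        df, _ = annotate_cells(cells, germline)
        t = UniqueBCRTable.from_airr(df)
        assert t.total_reads() > 2000
        om = overlap_coefficients(t, depth=2000, n_subsamples=10, seed=1)
        assert om.subsampled
        assert om.total() == pytest.approx(1.0)


class TestSwitchProbabilities:
    def test_hand_computed_ratios(self):
        # gene V1: 100 unique BCRs, 40 mutated, 30 of the mutated switched
        rows = []
        for i in range(100):
            mutated = i < 40
            switched = i < 30          # switched subset of the mutated
            iso = "IGHG1" if switched else "IGHM"
            rows.append((f"SEQ{i:03d}" + "A" * 10, iso, 2, "V1-S1", "J1",
                         f"C{i}", 1 if mutated else 0))
        t = UniqueBCRTable.from_airr(_airr(rows))
        spt = switch_probabilities(t, min_reads=100)
        row = spt.table.loc["V1-S1"]
        assert row["fx"] == 100
        assert row["p_mutated"] == pytest.approx(0.40)
        assert row["p_switched_mutated"] == pytest.approx(0.75)
        assert row["p_switched_unmutated"] == 0.0
        spt.verify_identities()

    def test_all_unmutated_igm_gives_zero_switch(self):
        rows = [(f"S{i}" + "A" * 10, "IGHM", 3, "V1-S1", "J1", f"C{i}", 0)
                for i in range(50)]
        t = UniqueBCRTable.from_airr(_airr(rows))
        spt = switch_probabilities(t, min_reads=100)
        assert (spt.table["p_switched"] == 0).all()

    def test_low_support_genes_filtered(self):
        rows = [("A" * 12, "IGHM", 5, "V1-S1", "J1", "X", 0),
                ("C" * 12, "IGHM", 500, "V2-S2", "J1", "Y", 0)]
        t = UniqueBCRTable.from_airr(_airr(rows))
        spt = switch_probabilities(t, min_reads=100)
        assert list(spt.table.index) == ["V2-S2"]

    def test_family_level_aggregation(self):
        rows = [("A" * 12, "IGHM", 200, "IGHV1-S1", "J1", "X", 0),
                ("C" * 12, "IGHG1", 200, "IGHV1-S8", "J1", "Y", 1)]
        t = UniqueBCRTable.from_airr(_airr(rows))
        spt = switch_probabilities(t, level="family", min_reads=100)
        assert list(spt.table.index) == ["IGHV1"]
        assert spt.table.loc["IGHV1", "fx"] == 2


class TestProfiles:
    def test_identical_usage_gives_unit_correlation(self):
        rows = []
        for g in ("IGHV1-S1", "IGHV2-S2", "IGHV3-S3"):
            n = {"IGHV1-S1": 30, "IGHV2-S2": 20, "IGHV3-S3": 10}[g]
            for i in range(n):
                for iso in ("IGHM", "IGHG1"):
                    rows.append((f"{g}{iso}{i}" + "A" * 6, iso, 10, g, "J1",
                                 f"C{g}{i}", 0))
        t = UniqueBCRTable.from_airr(_airr(rows))
        prof = ighv_isotype_profiles(t, min_reads=100)
        assert np.allclose(prof.profiles.sum(axis=0), 100.0)
        assert prof.correlation.loc["IgM", "IgG1/2"] == pytest.approx(1.0)

    def test_anticorrelated_usage_recovered(self):
        rng = np.random.default_rng(41)
        rows = []
        genes = [f"IGHV{(k % 7) + 1}-S{k:02d}" for k in range(30)]
        weights = np.linspace(1, 10, 30)
        for k, g in enumerate(genes):
            n_m = int(20 * weights[k])          # IgM prefers high-k genes
            n_g = int(20 * weights[29 - k])     # IgG prefers low-k genes
            for i in range(n_m):
                rows.append((f"{g}M{i}" + "A" * 6, "IGHM", 2, g, "J1",
                             f"M{g}{i}", 0))
            for i in range(n_g):
                rows.append((f"{g}G{i}" + "A" * 6, "IGHG1", 2, g, "J1",
                             f"G{g}{i}", 1))
        t = UniqueBCRTable.from_airr(_airr(rows))
        prof = ighv_isotype_profiles(t, min_reads=100)
        assert prof.correlation.loc["IgM", "IgG1/2"] < 0
        assert prof.correlation_p.loc["IgM", "IgG1/2"] < 0.05
        assert prof.nonrandomness.loc["IgG1/2", "p"] < 0.05


class TestCohortTests:
    def test_identical_groups_wilcoxon_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p_value"] == pytest.approx(1.0)
        assert res["degenerate"] is False

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, size=10)
        b = rng.normal(3, 1, size=10)   # 3 SD shift, n=10 per arm
        res = wilcoxon_rank_sum(a, b)
        assert res["p_value"] < 0.005

    def test_one_way_anova_detects_gene_effect(self):
        rng = np.random.default_rng(43)
        rows = []
        for gene, mu in (("V1", 0.2), ("V2", 0.5), ("V3", 0.8)):
            for _ in range(12):
                rows.append({"gene": gene,
                             "p_switched": rng.normal(mu, 0.05)})
        res = anova_one_way(pd.DataFrame(rows), "p_switched", "gene")
        assert res.loc["C(gene)", "PR(>F)"] < 0.001

    def test_two_way_anova_recovers_planted_interaction(self):
        rng = np.random.default_rng(44)
        rows = []
        for gene, base in (("V1", 0.2), ("V2", 0.4)):
            for mutated in (0, 1):
                # interaction: mutation boosts V1 far more than V2
                mu = base + (0.4 if (gene == "V1" and mutated) else 0.1 * mutated)
                for _ in range(15):
                    rows.append({"gene": gene, "mutated": mutated,
                                 "p_switched": rng.normal(mu, 0.05)})
        res = anova_two_way(pd.DataFrame(rows), "p_switched", "gene",
                            "mutated")
        assert res.loc["C(gene):C(mutated)", "PR(>F)"] < 0.05
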