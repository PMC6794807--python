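import numpy as np
import pandas as pd
import pytest

from oracles import all_pairs_cis, all_pairs_trans, scan_seed_sites
from ttrnet.data import ExpressionMatrix, TranscriptAnnotation, ValidationError
from ttrnet.networks import (
    TransEdge,
    cerna_triads,
    cis_pairs,
    find_all_sites,
    hub_rank,
    merge_networks,
    seed_match_sites,
    trans_pairs,
)


def _annotation(spans):
    """spans: id -> (biotype, chrom, start, end, strand)."""
    rows = {
        t: (t.split(".")[0], t.split(".")[0], bio, c, s, e, strand)
        for t, (bio, c, s, e, strand) in spans.items()
    }
    return TranscriptAnnotation(
        pd.DataFrame.from_dict(
            rows, orient="index", columns=list(TranscriptAnnotation.COLUMNS)
        ).rename_axis("transcript_id")
    )


class TestCisPairs:
    def test_downstream_pair_within_window(self):
        ann = _annotation(
            {
                "L.t1": ("lncRNA", "chr1", 20_000, 21_000, "+"),
                "M.t1": ("coding", "chr1", 25_000, 26_000, "+"),
            }
        )
        (pair,) = cis_pairs(ann, ["L.t1"], ["M.t1"], 10_000)
        assert pair.relation == "downstream" and pair.gap_bp == 4_000

    def test_intersecting_spans_are_overlapping_with_zero_gap(self):
        ann = _annotation(
            {
                "L.t1": ("lncRNA", "chr1", 1_000, 2_000, "-"),
                "M.t1": ("coding", "chr1", 1_500, 2_500, "+"),
            }
        )
        (pair,) = cis_pairs(ann, ["L.t1"], ["M.t1"], 10_000)
        assert pair.relation == "overlapping" and pair.gap_bp == 0
        assert pair.opposite_strand

    @pytest.mark.parametrize("gap,expected_n", [(10_000, 1), (10_001, 0)])
    def test_window_boundary_is_inclusive(self, gap, expected_n):
        ann = _annotation(
            {
                "L.t1": ("lncRNA", "chr1", 1_000, 2_000, "+"),
                "M.t1": ("coding", "chr1", 2_000 + gap, 3_000 + gap, "+"),
            }
        )
        assert len(cis_pairs(ann, ["L.t1"], ["M.t1"], 10_000)) == expected_n

    def test_different_chromosomes_never_pair(self):
        ann = _annotation(
            {
                "L.t1": ("lncRNA", "chr1", 1_000, 2_000, "+"),
                "M.t1": ("coding", "chr2", 2_500, 3_000, "+"),
            }
        )
        assert cis_pairs(ann, ["L.t1"], ["M.t1"], 10_000) == []

    def test_matches_brute_force_scan_on_synthetic_annotation(self, default_dataset):
        ann = default_dataset.annotation
        lnc, mrna = ann.lncrna_ids(), ann.coding_ids()
        called = {
            (p.lncrna_id, p.mrna_id): (p.relation, p.gap_bp)
            for p in cis_pairs(ann, lnc, mrna, 10_000)
        }
        oracle = all_pairs_cis(ann.table, lnc, mrna, 10_000)
        assert called == oracle
        # the planted boundary pair is in, the decoys are out
        for pair in default_dataset.truth.cis_boundary_pairs:
            assert pair in called and called[pair][1] == 10_000
        for pair in default_dataset.truth.cis_decoy_pairs:
            assert pair not in called

    def test_swapping_roles_inverts_the_relation(self, default_dataset):
        ann = default_dataset.annotation
        lnc, mrna = ann.lncrna_ids(), ann.coding_ids()
        fwd = {(p.lncrna_id, p.mrna_id): p.relation for p in cis_pairs(ann, lnc, mrna)}
        rev = {(p.mrna_id, p.lncrna_id): p.relation for p in cis_pairs(ann, mrna, lnc)}
        flip = {"upstream": "downstream", "downstream": "upstream", "overlapping": "overlapping"}
        for (a, b), relation in fwd.items():
            assert rev[(a, b)] == flip[relation]

    def test_missing_coordinates_are_skipped_not_fatal(self, default_dataset):
        ann = default_dataset.annotation
        pairs = cis_pairs(ann, ["not_a_transcript"], ann.coding_ids()[:5], 10_000)
        assert pairs == []


def _trans_matrix(seed=9):
    """Planted high-correlation pair plus a decoy at moderate correlation."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(9)]
    design = pd.Series({s: ["LG", "HG", "HG_TTR"][i // 3] for i, s in enumerate(samples)})
    base = rng.normal(5, 1, 9)
    lnc = base + rng.normal(0, 0.05, 9)          # r ~ 0.99 with base
    decoy = base * 0.5 + rng.normal(0, 1.2, 9)   # moderate r
    anti = 10 - base + rng.normal(0, 0.05, 9)    # r ~ -0.99
    values = np.exp2(np.vstack([lnc, base, decoy, anti])) - 1
    frame = pd.DataFrame(
        np.maximum(values, 1e-9),
        index=["lncA", "mrnaHit", "mrnaDecoy", "mrnaAnti"],
        columns=samples,
    )
    return ExpressionMatrix(frame, design)


class TestTransPairs:
    def test_identical_profile_gives_positive_unit_edge(self):
        m = _trans_matrix()
        m.values.loc["mrnaHit"] = m.values.loc["lncA"]
        edges = trans_pairs(m, ["lncA"], ["mrnaHit"], 0.95)
        assert len(edges) == 1 and edges[0].sign == "positive"
        assert edges[0].pearson_r == pytest.approx(1.0)

    def test_anti_proportional_profile_gives_negative_edge(self):
        m = _trans_matrix()
        log = m.log2p1()
        anti = -2.0 * log.loc["lncA"] + 20.0
        m.values.loc["mrnaAnti"] = np.exp2(anti) - 1
        edges = trans_pairs(m, ["lncA"], ["mrnaAnti"], 0.95)
        assert len(edges) == 1 and edges[0].sign == "negative"
        assert edges[0].pearson_r == pytest.approx(-1.0)

    def test_planted_pair_found_decoy_excluded_matches_oracle(self):
        m = _trans_matrix(seed=9)
        edges = trans_pairs(m, ["lncA"], ["mrnaHit", "mrnaDecoy", "mrnaAnti"], 0.95)
        called = {(e.lncrna_id, e.mrna_id): e.pearson_r for e in edges}
        oracle = all_pairs_trans(m.log2p1(), ["lncA"], ["mrnaHit", "mrnaDecoy", "mrnaAnti"], 0.95)
        assert set(called) == set(oracle)
        for k in called:
            assert called[k] == pytest.approx(oracle[k], abs=1e-12)
        assert ("lncA", "mrnaDecoy") not in called

    def test_threshold_monotonicity(self, default_dataset):
        m = default_dataset.matrix
        ann = default_dataset.annotation
        lnc, mrna = ann.lncrna_ids(), ann.coding_ids()
        tight = {(e.lncrna_id, e.mrna_id) for e in trans_pairs(m, lnc, mrna, 0.97)}
        loose = {(e.lncrna_id, e.mrna_id) for e in trans_pairs(m, lnc, mrna, 0.95)}
        assert tight <= loose

    def test_matches_brute_force_on_synthetic_data(self, default_dataset):
        m = default_dataset.matrix
        ann = default_dataset.annotation
        lnc, mrna = ann.lncrna_ids()[:20], ann.coding_ids()[:100]
        called = {(e.lncrna_id, e.mrna_id) for e in trans_pairs(m, lnc, mrna, 0.95)}
        oracle = set(all_pairs_trans(m.log2p1(), lnc, mrna, 0.95))
        assert called == oracle

    def test_empty_sets_give_empty_output(self, default_dataset):
        assert trans_pairs(default_dataset.matrix, [], [], 0.95) == []


LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestSeedMatcher:
    def test_let7_8mer_site(self):
        (site,) = seed_match_sites("GGGCTACCTCAGGG", LET7)
        assert site.match_type == "8mer" and site.start == 5

    @pytest.mark.parametrize(
        "target,expected",
        [
            ("GGCTACCTCAGG", "8mer"),     # m8 complement + A1
            ("GGCTACCTCTGG", "7mer-m8"),  # m8 complement, no A
            ("GGTTACCTCAGG", "7mer-A1"),  # A1 only
            ("GGTTACCTCTGG", "6mer"),     # bare core
        ],
    )
    def test_site_classification(self, target, expected):
        (site,) = seed_match_sites(target, LET7)
        assert site.match_type == expected

    def test_seed_only_input_is_equivalent_to_full_mirna(self):
        full = seed_match_sites("GGCTACCTCAGG", LET7)
        seed = seed_match_sites("GGCTACCTCAGG", "GAGGUAG")
        assert [(s.start, s.match_type) for s in full] == [
            (s.start, s.match_type) for s in seed
        ]

    def test_target_without_complement_yields_nothing(self):
        assert seed_match_sites("A" * 40, LET7) == []

    def test_two_planted_sites_both_reported(self):
        target = "GG" + "CTACCTCA" + "GGGGG" + "CTACCTCA" + "GG"
        sites = seed_match_sites(target, LET7)
        assert [(s.start, s.match_type) for s in sites] == [(4, "8mer"), (17, "8mer")]

    def test_u_and_t_equivalent_and_bad_characters_rejected(self):
        a = seed_match_sites("GGCUACCUCAGG", LET7)
        b = seed_match_sites("GGCTACCTCAGG", LET7.replace("U", "T"))
        assert [(s.start, s.match_type) for s in a] == [(s.start, s.match_type) for s in b]
        with pytest.raises(ValidationError):
            seed_match_sites("ACGTX", LET7)

    def test_matches_exhaustive_substring_scan_on_random_draws(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            target = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, 22))
            got = [(s.start, s.match_type) for s in seed_match_sites(target, mirna)]
            assert got == scan_seed_sites(target, mirna)


class TestCeRNATriads:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["mirna_id", "target_id", "start", "match_type"])

    def test_shared_mirna_forms_a_triad(self):
        lnc = self._sites([("mirX", "L1", 3, "8mer")])
        mrna = self._sites([("mirX", "M1", 9, "7mer-m8")])
        (triad,) = cerna_triads(lnc, mrna)
        assert (triad.lncrna_id, triad.mirna_id, triad.mrna_id) == ("L1", "mirX", "M1")
        assert triad.lnc_site_count == 1 and triad.mrna_site_count == 1

    def test_unshared_mirnas_form_nothing(self):
        lnc = self._sites([("mirX", "L1", 3, "8mer")])
        mrna = self._sites([("mirY", "M1", 9, "8mer")])
        assert cerna_triads(lnc, mrna) == []

    def test_min_sites_gate(self):
        lnc = self._sites([("mirX", "L1", 3, "8mer"), ("mirX", "L1", 30, "6mer")])
        mrna = self._sites([("mirX", "M1", 9, "8mer")])
        assert len(cerna_triads(lnc, mrna, min_sites=1)) == 1
        assert cerna_triads(lnc, mrna, min_sites=2) == []

    def test_planted_triads_recovered_perfectly(self, default_dataset):
        ds = default_dataset
        lnc_seq = {t: ds.sequences[t] for t in ds.annotation.lncrna_ids()}
        mrna_seq = {t: ds.sequences[t] for t in ds.annotation.coding_ids()}
        triads = cerna_triads(
            find_all_sites(lnc_seq, ds.seed_table),
            find_all_sites(mrna_seq, ds.seed_table),
        )
        called = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triads}
        assert called == set(ds.truth.planted_triads)


class TestHubRank:
    def test_star_network_puts_the_hub_first(self):
        edges = [TransEdge("L1", f"M{i}", 0.99) for i in range(5)]
        edges += [TransEdge("L2", "M0", 0.99)]
        table = hub_rank(edges)
        assert list(table["lncrna_id"]) == ["L1", "L2"]
        assert table["degree"].tolist() == [5, 1]

    def test_equal_degrees_rank_lexicographically(self):
        edges = [TransEdge(l, "M1", 0.99) for l in ("Lb", "La", "Lc")]
        assert list(hub_rank(edges)["lncrna_id"]) == ["La", "Lb", "Lc"]

    def test_degree_counts_unique_partners(self):
        edges = [TransEdge("L1", "M1", 0.99), TransEdge("L1", "M1", -0.99)]
        assert hub_rank(edges)["degree"].tolist() == [1]

    def test_matches_brute_force_degree_count(self, default_dataset):
        m = default_dataset.matrix
        ann = default_dataset.annotation
        edges = trans_pairs(m, ann.lncrna_ids(), ann.coding_ids(), 0.95)
        table = hub_rank(edges, top_n=1000)
        brute = {}
        for e in edges:
            brute.setdefault(e.lncrna_id, set()).add(e.mrna_id)
        assert dict(zip(table["lncrna_id"], table["degree"])) == {
            k: len(v) for k, v in brute.items()
        }

    def test_empty_network_gives_empty_ranking(self):
        assert hub_rank([]).empty


class TestMergeNetworks:
    def test_all_three_edge_types_and_mirna_bridge(self):
        from ttrnet.networks import CeRNATriad, CisPair

        cis = [CisPair("L1", "M1", "downstream", 500, False)]
        trans = [TransEdge("L1", "M2", 0.99)]
        triads = [CeRNATriad("L1", "mirX", "M3", 1, 2)]
        g = merge_networks(cis, trans, triads, ["L1"])
        kinds = {d["type"] for _, _, d in g.edges(data=True)}
        assert kinds == {"cis", "trans", "ceRNA"}
        assert g.nodes["mirX"]["kind"] == "miRNA"
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 4

    def test_focus_without_relations_stays_isolated(self):
        g = merge_networks([], [], [], ["L9"])
        assert set(g.nodes) == {"L9"} and g.number_of_edges() == 0

    def test_empty_focus_rejected(self):
        with pytest.raises(ValidationError):
            merge_networks([], [], [], [])

    def test_counts_match_hand_tally_on_synthetic_truth(self, default_dataset):
        ds = default_dataset
        ann = ds.annotation
        cis = cis_pairs(ann, ann.lncrna_ids(), ann.coding_ids(), 10_000)
        lnc_seq = {t: ds.sequences[t] for t in ann.lncrna_ids()}
        mrna_seq = {t: ds.sequences[t] for t in ann.coding_ids()}
        triads = cerna_triads(
            find_all_sites(lnc_seq, ds.seed_table),
            find_all_sites(mrna_seq, ds.seed_table),
        )
        focus = ds.truth.planted_triads[0][0]  # a triad lncRNA
        g = merge_networks(cis, [], triads, [focus])
        expected_triads = [t for t in ds.truth.planted_triads if t[0] == focus]
        expected_cis = [p for p in ds.truth.cis_pairs if p[0] == focus]
        assert g.number_of_edges() == 2 * len(expected_triads) + len(expected_cis)
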