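import numpy as np
import pandas as pd
import pytest

from paa.errors import NotFoundError, PaaError, ValidationError
from paa.screen_io import MeasurementKind, ScreenMatrix, SequenceMap
from paa.substrate_db import (
    SubstrateDatabase,
    build_database,
    levenshtein_distance,
    load_ortholog_table,
    partial_ratio,
    query_protease,
    query_sequence,
    query_substrate,
    search_kmer,
    similarity_matrix,
    similarity_ratio,
    species_to_species,
    summarize_database,
)


from oracles import all_windows_partial_ratio, brute_force_edit_distance, random_peptides

# ---------------------------------------------------------------------------
# edit distance / ratios
# ---------------------------------------------------------------------------

class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("PLGL", "PLGL", 0),
            ("GGPLGL", "GSPLGL", 1),
            ("", "", 0),
            ("AAAA", "", 4),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert levenshtein_distance(a, b) == expected

    def test_matches_recursive_oracle(self, rng):
        pairs = zip(random_peptides(rng, 60, 6), random_peptides(rng, 60, 6))
        for a, b in pairs:
            assert levenshtein_distance(a, b) == brute_force_edit_distance(a, b)

    def test_matches_edlib(self, rng):
        edlib = pytest.importorskip("edlib")
        for a, b in zip(random_peptides(rng, 40, 12, 1), random_peptides(rng, 40, 12, 1)):
            assert levenshtein_distance(a, b) == edlib.align(a, b)["editDistance"]

    def test_metric_properties(self, rng):
        seqs = random_peptides(rng, 12, 5)
        for a in seqs:
            assert levenshtein_distance(a, a) == 0
            for b in seqs:
                assert levenshtein_distance(a, b) == levenshtein_distance(b, a)
                for c in seqs:
                    assert levenshtein_distance(a, c) <= (
                        levenshtein_distance(a, b) + levenshtein_distance(b, c)
                    )


class TestSimilarityRatios:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("PLGL", "PLGL", 1.0),
            ("AAAA", "", 0.0),
            ("GGPLGL", "GSPLGL", 5 / 6),
            ("", "", 1.0),
        ],
    )
    def test_ratio_known_values(self, a, b, expected):
        assert similarity_ratio(a, b) == pytest.approx(expected)

    def test_partial_ratio_exact_substring_is_one(self):
        assert partial_ratio("PLG", "GGPLGL") == 1.0

    def test_partial_ratio_equal_length_equals_ratio(self, rng):
        for a, b in zip(random_peptides(rng, 20, 6, 1), random_peptides(rng, 20, 6, 6)):
            b = b[: len(a)] if len(a) <= len(b) else b
            if len(a) == len(b):
                assert partial_ratio(a, b) == pytest.approx(similarity_ratio(a, b))

    def test_partial_ratio_matches_window_oracle(self, rng):
        for a, b in zip(random_peptides(rng, 60, 8, 1), random_peptides(rng, 60, 8, 1)):
            assert partial_ratio(a, b) == pytest.approx(all_windows_partial_ratio(a, b))

    def test_bounds(self, rng):
        for a, b in zip(random_peptides(rng, 30, 8), random_peptides(rng, 30, 8, 1)):
            assert 0.0 <= similarity_ratio(a, b) <= 1.0
            assert 0.0 <= partial_ratio(a, b) <= 1.0


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

def _screen(name, subs, prots, values, kind=MeasurementKind.fold_change):
    return ScreenMatrix(name, pd.DataFrame(values, index=subs, columns=prots), kind)


class TestBuildDatabase:
    def test_single_screen(self, toy_db):
        assert len(toy_db.substrate_index) == 3
        assert len(toy_db.protease_index) == 3

    def test_set_union_over_screens(self):
        s1 = _screen("a", ["S1", "S2", "S3"], ["P1"], [[1.0], [2.0], [3.0]])
        s2 = _screen("b", ["S3", "S4", "S5"], ["P2"], [[1.0], [2.0], [3.0]])
        seqs = SequenceMap({f"S{i}": "GGPLGLGG" for i in range(1, 6)})
        db = build_database([s1, s2], seqs)
        assert len(db.substrate_index) == 5
        # the shared substrate carries data from both screens
        assert set(db.substrate_index["s3"]) == {"a", "b"}

    def test_indexed_values_match_input_cells(self, toy_db, toy_screen):
        for sub in toy_screen.substrate_labels:
            for prot in toy_screen.condition_labels:
                assert (
                    toy_db.substrate_index[sub.casefold()]["toy"][prot.casefold()]
                    == toy_screen.values.at[sub, prot]
                )

    def test_zero_screens_rejected(self, toy_sequences):
        with pytest.raises(ValueError):
            build_database([], toy_sequences)

    def test_missing_sequences_warn_or_error(self, toy_screen):
        seqs = SequenceMap({"S1": "GGPLGL"})
        with pytest.warns(UserWarning, match="without a sequence"):
            build_database([toy_screen], seqs)
        with pytest.raises(ValidationError):
            build_database([toy_screen], seqs, missing_sequence="error")

    def test_json_round_trip(self, toy_db, tmp_path):
        toy_db.to_json(tmp_path / "db.json")
        back = SubstrateDatabase.from_json(tmp_path / "db.json")
        assert back.substrate_index == toy_db.substrate_index
        assert dict(back.sequences.items()) == dict(toy_db.sequences.items())


# ---------------------------------------------------------------------------
# ranked queries
# ---------------------------------------------------------------------------

class TestRankedQueries:
    def test_single_cell_database_scores_zero(self):
        db = build_database(
            [_screen("one", ["S1"], ["P1"], [[5.0]])], SequenceMap({"S1": "PLGL"})
        )
        res = query_protease(db, "P1", top_k=3)
        assert len(res.rows) == 1
        assert res.rows[0].rank == 1
        assert res.rows[0].combined_score == 0.0

    def test_dominant_cell_ranks_first_both_directions(self, toy_db):
        by_prot = query_protease(toy_db, "P2", top_k=3)
        assert by_prot.rows[0].label == "S2"
        by_sub = query_substrate(toy_db, "S2", top_k=3)
        assert by_sub.rows[0].label == "P2"

    def test_hand_computed_z_scores(self, toy_db):
        # column P2 = [1, 100, 1]: mean 34, sd 57.157...; eff z of S2:
        col = np.array([1.0, 100.0, 1.0])
        eff = (100 - col.mean()) / col.std(ddof=1)
        row = np.array([1.0, 100.0, 1.0])
        spec = (100 - row.mean()) / row.std(ddof=1)
        res = query_protease(toy_db, "P2", top_k=1)
        assert res.rows[0].combined_score == pytest.approx((eff + spec) / 2)

    def test_constant_column_yields_zero_efficiency(self, toy_db):
        res = query_protease(toy_db, "P1", top_k=3)  # column all 1.0
        for row in res.rows:
            assert row.efficiency_z["toy"] == 0.0

    def test_case_insensitive_match_and_near_miss_suggestion(self, toy_db):
        assert query_protease(toy_db, " p2 ", top_k=1).rows[0].label == "S2"
        with pytest.raises(NotFoundError, match="P1"):
            query_protease(toy_db, "P1X", top_k=1)

    def test_top_k_validation(self, toy_db):
        with pytest.raises(ValueError):
            query_protease(toy_db, "P1", top_k=0)

    def test_ranking_invariant_to_permutation(self, toy_screen, toy_sequences, rng):
        perm_rows = rng.permutation(toy_screen.substrate_labels)
        perm_cols = rng.permutation(toy_screen.condition_labels)
        permuted = ScreenMatrix(
            "toy", toy_screen.values.loc[perm_rows, perm_cols], toy_screen.measurement_kind
        )
        db1 = build_database([toy_screen], toy_sequences)
        db2 = build_database([permuted], toy_sequences)
        r1 = query_protease(db1, "P2", top_k=3)
        r2 = query_protease(db2, "P2", top_k=3)
        assert [(r.label, r.rank) for r in r1.rows] == [(r.label, r.rank) for r in r2.rows]
        for a, b in zip(r1.rows, r2.rows):
            assert a.combined_score == pytest.approx(b.combined_score)


# ---------------------------------------------------------------------------
# sequence search
# ---------------------------------------------------------------------------

class TestSequenceSearch:
    def test_exact_match_first(self, toy_db):
        hits = query_sequence(toy_db, "GGPLGLGG", k=3)
        assert hits[0].substrate_label == "S1"
        assert hits[0].ratio == 1.0 and hits[0].edit_distance == 0

    def test_k_larger_than_database(self, toy_db):
        hits = query_sequence(toy_db, "PLGL", k=100)
        assert len(hits) == len(toy_db.sequences)
        metrics = [h.ratio for h in hits]
        assert metrics == sorted(metrics, reverse=True)

    def test_ordering_matches_pairwise_oracle(self, toy_db):
        query = "GGPLAL"
        hits = query_sequence(toy_db, query, k=5, metric="partial_ratio")
        oracle = sorted(
            toy_db.sequences.items(),
            key=lambda kv: (
                -all_windows_partial_ratio(query, kv[1]),
                -similarity_ratio(query, kv[1]),
                kv[0],
            ),
        )
        assert [h.substrate_label for h in hits] == [label for label, _ in oracle]

    def test_kmer_absent_returns_empty(self, toy_db):
        assert search_kmer(toy_db, "WWWW") == []

    def test_kmer_planted_position(self, toy_db):
        hits = search_kmer(toy_db, "PLGL")
        assert [(h[0], h[2]) for h in hits] == [("S1", [2]), ("S4", [2])]

    def test_kmer_overlapping_matches(self):
        db = build_database(
            [_screen("x", ["S1"], ["P1"], [[1.0]])], SequenceMap({"S1": "AAAA"})
        )
        assert search_kmer(db, "AA")[0][2] == [0, 1, 2]

    def test_kmer_equals_naive_scan(self, toy_db):
        for kmer in ["GG", "PL", "A", "GGP"]:
            naive = sorted(
                (label, [i for i in range(len(seq) - len(kmer) + 1) if seq[i : i + len(kmer)] == kmer])
                for label, seq in toy_db.sequences.items()
            )
            naive = [(l, p) for l, p in naive if p]
            assert [(h[0], h[2]) for h in search_kmer(toy_db, kmer)] == naive


class TestSimilarityMatrix:
    def test_identical_pair_merges_first(self):
        db = build_database(
            [_screen("x", ["A", "B", "C"], ["P1"], [[1.0], [1.0], [1.0]])],
            SequenceMap({"A": "GGPLGL", "B": "GGPLGL", "C": "WWWWWW"}),
        )
        mat, order, Z = similarity_matrix(db)
        # first merge joins the two identical sequences (distance 0)
        assert Z[0, 2] == 0.0
        first = {int(Z[0, 0]), int(Z[0, 1])}
        labels = sorted(db.sequences.entries)
        assert {labels[i] for i in first} == {"A", "B"}

    def test_diagonal_one_and_symmetry(self, toy_db):
        mat, _, _ = similarity_matrix(toy_db)
        np.testing.assert_array_equal(np.diag(mat.to_numpy()), 1.0)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_permutation_invariant_topology(self, toy_screen, toy_sequences):
        from scipy.cluster.hierarchy import cophenet

        db = build_database([toy_screen], toy_sequences)
        mat1, _, Z1 = similarity_matrix(db)
        # rebuilding with a permuted sequence map must give identical
        # cophenetic structure on the (sorted) labels
        shuffled = SequenceMap(dict(reversed(list(toy_sequences.items()))))
        db2 = build_database([toy_screen], shuffled)
        mat2, _, Z2 = similarity_matrix(db2)
        np.testing.assert_allclose(cophenet(Z1), cophenet(Z2))

    def test_too_few_sequences_raise(self):
        db = build_database(
            [_screen("x", ["S1"], ["P1"], [[1.0]])], SequenceMap({"S1": "PLGL"})
        )
        with pytest.raises(PaaError):
            similarity_matrix(db)


# ---------------------------------------------------------------------------
# species mapping & summaries
# ---------------------------------------------------------------------------

class TestSpeciesMapping:
    def test_human_mmp9_to_mouse(self):
        assert species_to_species("MMP9", "human", "mouse") == "Mmp9"

    def test_gzmh_has_no_mouse_ortholog(self):
        assert species_to_species("GZMH", "human", "mouse") is None

    def test_identity_mapping(self):
        assert species_to_species("MMP13", "human", "human") == "MMP13"

    def test_unknown_gene_raises_not_found(self):
        with pytest.raises(NotFoundError):
            species_to_species("NOTAGENE", "human", "mouse")

    def test_user_supplied_table(self, tmp_path):
        p = tmp_path / "orth.csv"
        p.write_text("human,chimpanzee,mouse,rat\nTESTG,TESTG,Testg,Testg\n")
        table = load_ortholog_table(p)
        assert species_to_species("TESTG", "human", "rat", table) == "Testg"


class TestSummaries:
    def test_single_screen_counts(self):
        db = build_database(
            [_screen("x", ["S1", "S2"], ["P1", "P2", "P3"], np.ones((2, 3)))],
            SequenceMap({"S1": "PLGL", "S2": "VPLS"}),
        )
        s = summarize_database(db)
        assert s["per_screen"]["x"] == {"n_substrates": 2, "n_proteases": 3}

    def test_disjoint_union(self):
        s1 = _screen("a", ["S1", "S2"], ["P1", "P2"], np.ones((2, 2)))
        s2 = _screen("b", ["S3", "S4"], ["P3", "P4"], np.ones((2, 2)))
        seqs = SequenceMap({f"S{i}": "PLGL" for i in range(1, 5)})
        s = summarize_database(build_database([s1, s2], seqs))
        assert s["n_unique_substrates"] == 4 and s["n_unique_proteases"] == 4

    def test_class_composition(self, toy_screen, toy_sequences):
        db = build_database(
            [toy_screen],
            toy_sequences,
            protease_classes={"P1": "metallo", "P2": "metallo", "P3": "serine"},
        )
        assert summarize_database(db)["class_composition"] == {"metallo": 2, "serine": 1}
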