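"""Pairwise similarity, cluster coherence, permutation null, rank-sum test."""

import itertools

import numpy as np
import pytest

import tcmnet as t
from tcmnet.errors import AnnotationError, ValidationError
from tcmnet.validation import bigram_tokenizer


def make_partition(assignment):
    return t.Partition(dict(assignment), modularity=0.0, algorithm="test")


class TestPairSimilarity:
    def test_identical_payloads_score_one(self):
        assert t.pair_similarity({"a", "b"}, {"a", "b"}, "label_set") == 1.0
        assert t.pair_similarity("CCO", "CCO", "string") == 1.0

    def test_disjoint_payloads_score_zero(self):
        assert t.pair_similarity({"a"}, {"b"}, "id_set") == 0.0
        assert t.pair_similarity("CC", "NN", "string") == 0.0

    def test_overlap_and_jaccard_hand_example(self):
        a, b = {"a", "b"}, {"b", "c", "d"}
        assert t.pair_similarity(a, b, "label_set") == pytest.approx(0.5)
        assert t.pair_similarity(a, b, "label_set", metric="jaccard") == pytest.approx(0.25)

    def test_dice_of_cco_ccn_bigrams(self):
        # T(CCO)={CC,CO}, T(CCN)={CC,CN} -> 2*1/4
        assert t.pair_similarity("CCO", "CCN", "string") == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        labels = list("abcdef")
        for _ in range(20):
            a = set(rng.choice(labels, rng.integers(1, 5), replace=False))
            b = set(rng.choice(labels, rng.integers(1, 5), replace=False))
            for metric in ("overlap", "jaccard"):
                assert t.pair_similarity(a, b, "label_set", metric=metric) == \
                    t.pair_similarity(b, a, "label_set", metric=metric)

    def test_empty_payload_raises(self):
        with pytest.raises(AnnotationError):
            t.pair_similarity(set(), {"a"}, "label_set")
        with pytest.raises(AnnotationError):
            t.pair_similarity("", "CC", "string")

    def test_overlap_is_one_iff_containment_dice_one_iff_equal(self):
        # exhaustive over all non-empty subsets of a 5-token universe
        universe = list(range(5))
        subsets = [
            frozenset(c)
            for r in range(1, 6)
            for c in itertools.combinations(universe, r)
        ]
        for a, b in itertools.product(subsets, repeat=2):
            ov = t.pair_similarity(a, b, "id_set", metric="overlap")
            dc = t.pair_similarity(a, b, "id_set", metric="dice")
            assert (ov == 1.0) == (a <= b or b <= a)
            assert (dc == 1.0) == (a == b)
            assert 0.0 <= ov <= 1.0 and 0.0 <= dc <= 1.0

    def test_custom_tokenizer_plug_in(self):
        # token = individual character instead of bigram
        sim = t.pair_similarity("AB", "BA", "string", tokenizer=lambda s: set(s))
        assert sim == 1.0

    def test_single_character_string_is_its_own_token(self):
        assert bigram_tokenizer("C") == frozenset({"C"})
        assert t.pair_similarity("C", "C", "string") == 1.0


class TestClusterSimilarity:
    def test_identical_pair_scores_one(self):
        p = make_partition({"x": 0, "y": 0})
        ann = t.AnnotationTable("label_set", {"x": {"a"}, "y": {"a"}})
        out = t.cluster_similarity(p, ann)
        assert len(out) == 1 and out[0].mean_similarity == 1.0

    def test_three_member_hand_enumeration(self):
        p = make_partition({"x": 0, "y": 0, "z": 0})
        ann = t.AnnotationTable("label_set", {"x": {"a"}, "y": {"a"}, "z": {"b"}})
        out = t.cluster_similarity(p, ann)
        assert out[0].mean_similarity == pytest.approx(1 / 3)

    def test_all_singleton_clusters_raise(self):
        p = make_partition({"x": 0, "y": 1})
        ann = t.AnnotationTable("label_set", {"x": {"a"}, "y": {"a"}})
        with pytest.raises(ValidationError):
            t.cluster_similarity(p, ann)

    def test_unannotated_members_are_excluded_not_dropped_silently(self):
        p = make_partition({"x": 0, "y": 0, "z": 0, "w": 1, "v": 1})
        ann = t.AnnotationTable("label_set", {"x": {"a"}, "y": {"a"}, "w": {"b"}})
        out = t.cluster_similarity(p, ann)  # cluster 1 has 1 annotated member
        assert [cs.cluster for cs in out] == [0]
        assert out[0].n_members == 3 and out[0].n_annotated == 2

    @pytest.mark.parametrize("kind,metric", [
        ("label_set", "overlap"), ("label_set", "jaccard"), ("string", "dice"),
    ])
    def test_matches_scalar_pairwise_mean(self, kind, metric, default_dataset):
        _, anns, truth = default_dataset
        if kind == "string":
            ann, block = anns["smiles"], truth.ingredient_block
        else:
            ann, block = anns["meridian"], truth.herb_block
        p = make_partition(block)
        out = t.cluster_similarity(p, ann, metric=metric)
        for cs in out[:2]:
            members = [
                e for e in sorted(p.assignment)
                if p.assignment[e] == cs.cluster and e in ann.payload
            ]
            sims = [
                t.pair_similarity(ann.payload[a], ann.payload[b], kind, metric=metric)
                for a, b in itertools.combinations(members, 2)
            ]
            assert cs.mean_similarity == pytest.approx(np.mean(sims), abs=1e-12)


class TestRandomGroupingNull:
    def test_identical_annotations_give_constant_null(self):
        p = make_partition({"a": 0, "b": 0, "c": 1, "d": 1})
        ann = t.AnnotationTable("label_set", {e: {"x"} for e in "abcd"})
        null = t.random_grouping_null(p, ann, n_replicates=5, seed=0)
        assert np.all(null == 1.0)

    def test_null_length_is_replicates_times_clusters(self):
        p = make_partition({"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2})
        ann = t.AnnotationTable(
            "label_set", {e: {e} for e in "abcdef"}
        )
        null = t.random_grouping_null(p, ann, n_replicates=2, seed=0)
        assert null.shape == (2 * 3,)

    def test_block_structure_beats_null_median(self, default_dataset):
        _, anns, truth = default_dataset
        p = make_partition(truth.herb_block)
        obs = t.cluster_similarity(p, anns["meridian"])
        null = t.random_grouping_null(p, anns["meridian"], n_replicates=50, seed=1)
        assert np.median([cs.mean_similarity for cs in obs]) > np.median(null)

    def test_deterministic_given_seed(self, default_dataset):
        _, anns, truth = default_dataset
        p = make_partition(truth.herb_block)
        a = t.random_grouping_null(p, anns["meridian"], n_replicates=3, seed=9)
        b = t.random_grouping_null(p, anns["meridian"], n_replicates=3, seed=9)
        assert np.array_equal(a, b)


class TestRankSumTest:
    def test_identical_samples_give_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0] * 4
        _, p = t.rank_sum_test(x, x)
        assert p > 0.9

    def test_exact_enumeration_hand_case(self):
        stat, p = t.rank_sum_test([1, 2, 3], [10, 11, 12])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_singleton_vs_singleton(self):
        _, p = t.rank_sum_test([1], [2])
        assert p == pytest.approx(1.0)

    def test_empty_sample_raises(self):
        with pytest.raises(ValidationError):
            t.rank_sum_test([], [1.0])

    def test_switches_to_asymptotic_with_ties(self):
        # ties force the normal approximation; p stays in (0, 1]
        _, p = t.rank_sum_test([1, 1, 2], [2, 3, 3])
        assert 0.0 < p <= 1.0


class TestValidate:
    def test_noise_free_planted_data_has_observed_median_one(self):
        cfg = t.SyntheticConfig(annotation_noise=0.0, seed=2)
        _, anns, truth = t.generate_dataset(cfg)
        p = make_partition(truth.herb_block)
        rep = t.validate(p, anns["meridian"], n_replicates=10, seed=0)
        assert rep.observed_median == 1.0
        assert rep.observed_median > rep.null_median

    def test_report_bookkeeping(self, default_dataset):
        _, anns, truth = default_dataset
        p = make_partition(truth.ingredient_block)
        rep = t.validate(p, anns["target"], n_replicates=7, seed=3)
        assert len(rep.null_values) == 7 * len(rep.observed)
        assert rep.n_replicates == 7 and rep.seed == 3
        assert 0.0 < rep.p_value <= 1.0
        assert rep.kind == "id_set" and rep.metric == "overlap"

    def test_observed_median_invariant_to_relabeling_and_renaming(self, default_dataset):
        _, anns, truth = default_dataset
        p1 = make_partition(truth.herb_block)
        rep1 = t.validate(p1, anns["meridian"], n_replicates=5, seed=1)
        # permute community labels
        relabel = {0: 2, 1: 0, 2: 1}
        p2 = make_partition({e: relabel[b] for e, b in truth.herb_block.items()})
        rep2 = t.validate(p2, anns["meridian"], n_replicates=5, seed=1)
        assert rep2.observed_median == pytest.approx(rep1.observed_median)
        # rename entities consistently in partition and annotation
        rename = {e: f"Q{e}" for e in truth.herb_block}
        p3 = make_partition({rename[e]: b for e, b in truth.herb_block.items()})
        ann3 = t.AnnotationTable(
            "label_set", {rename[e]: v for e, v in anns["meridian"].payload.items()}
        )
        rep3 = t.validate(p3, ann3, n_replicates=5, seed=1)
        assert rep3.observed_median == pytest.approx(rep1.observed_median)

    def test_similarity_values_all_in_unit_interval(self, default_dataset):
        _, anns, truth = default_dataset
        p = make_partition(truth.ingredient_block)
        rep = t.validate(p, anns["smiles"], n_replicates=5, seed=4)
        vals = [cs.mean_similarity for cs in rep.observed] + rep.null_values
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_report_json_and_tsv_outputs(self, tmp_path, default_dataset):
        _, anns, truth = default_dataset
        p = make_partition(truth.herb_block)
        rep = t.validate(p, anns["property"], n_replicates=4, seed=0)
        rep.write_json(tmp_path / "v.json")
        rep.write_values_tsv(tmp_path / "v.tsv")
        import json
        data = json.loads((tmp_path / "v.json").read_text())
        assert data["metric"] == "overlap" and data["n_replicates"] == 4
        lines = (tmp_path / "v.tsv").read_text().strip().splitlines()
        assert lines[0] == "group\tvalue"
        assert len(lines) == 1 + len(rep.observed) + len(rep.null_values)


def test_annotation_table_rejects_empty_payloads():
    with pytest.raises(AnnotationError):
        t.AnnotationTable("label_set", {"x": set()})
    with pytest.raises(AnnotationError):
        t.AnnotationTable("string", {"x": ""})
    with pytest.raises(AnnotationError):
        t.AnnotationTable("picture", {"x": {"a"}})


def test_annotation_table_tsv_roundtrip(tmp_path, default_dataset):
    _, anns, _ = default_dataset
    for name in ("meridian", "smiles", "target"):
        path = tmp_path / f"{name}.tsv"
        anns[name].write(path)
        back = t.AnnotationTable.read(path, anns[name].kind)
        assert back.payload == anns[name].payload
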