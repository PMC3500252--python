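import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetylsite import (
    FeatureEncoder,
    KnnConfig,
    PropertyIndex,
    assemble_features,
    binary_encode,
    fragment_distance,
    generate_fragments,
    knn_feature_vector,
    knn_score,
    normalize_substitution_matrix,
    property_encode,
    screen_property_indices,
)
from acetylsite.alphabet import AMINO_ACIDS
from acetylsite.corpus import WindowSpec
from acetylsite.encoding import code_matrix, distance_matrix, knn_score_matrix
from acetylsite.synthetic import MotifSpec, SyntheticDatasetSpec

from conftest import make_fragment, random_fragments

residue_strings = st.text(alphabet=AMINO_ACIDS + "X", min_size=1, max_size=25)


class TestBinaryEncoding:
    def test_printed_examples(self):
        assert binary_encode("A").tolist() == [1.0] + [0.0] * 19
        assert binary_encode("C").tolist() == [0.0, 1.0] + [0.0] * 18

    def test_dimension_is_20_per_position(self):
        assert binary_encode("ACDEFGHIKLMNP").shape == (260,)

    def test_pad_encodes_all_zero(self):
        assert not binary_encode("X").any()

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            binary_encode("AB")

    @given(residue_strings)
    @settings(max_examples=50, deadline=None)
    def test_one_hot_structure(self, s):
        v = binary_encode(s)
        blocks = v.reshape(len(s), 20)
        for ch, block in zip(s, blocks):
            assert block.sum() == (0 if ch == "X" else 1)


class TestPropertyEncoding:
    def test_all_pad_is_zero(self, janin):
        assert not property_encode("X" * 5, janin).any()

    def test_length_matches_positions(self, janin):
        assert property_encode("ACDEFGHIKLMNP", janin).shape == (13,)

    def test_minmax_endpoints(self, janin):
        best = max(janin.values, key=janin.values.get)
        worst = min(janin.values, key=janin.values.get)
        assert property_encode(best, janin)[0] == 1.0
        assert property_encode(worst, janin)[0] == 0.0

    def test_raw_scaling_keeps_magnitudes(self, janin):
        assert property_encode("K", janin, scaling="none")[0] == janin.values["K"]

    def test_missing_residue_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PropertyIndex("partial", {"A": 1.0})


class TestSubstitutionSimilarity:
    def test_blosum62_extremes(self, sim):
        assert sim.similarity("W", "W") == 1.0
        assert sim.similarity("A", "A") == pytest.approx(8 / 15)
        assert sim.raw.min() == -4 and sim.raw.max() == 11
        assert sim.sim.min() == 0.0

    def test_pad_similarity_zero(self, sim):
        assert sim.similarity("X", "W") == 0.0
        assert sim.similarity("X", "X") == 0.0

    def test_symmetry_required(self):
        M = np.zeros((20, 20))
        M[0, 1] = 3
        with pytest.raises(ValueError, match="symmetric"):
            normalize_substitution_matrix(M)

    def test_diagonal_is_row_maximum(self, sim):
        # guarantees an identical sequence minimizes the fragment distance
        assert (np.diag(sim.sim) >= sim.sim.max(axis=1) - 1e-12).all()


class TestFragmentDistance:
    def test_derived_values(self, sim):
        assert fragment_distance("KK", "KK", sim) == pytest.approx(0.4)
        assert fragment_distance("KK", "AA", sim) == pytest.approx(0.8)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_bounded(self, sim, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, 9))
        s2 = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, 9))
        d12, d21 = fragment_distance(s1, s2, sim), fragment_distance(s2, s1, sim)
        assert d12 == d21 and 0.0 <= d12 <= 1.0

    def test_self_distance_is_minimal(self, sim):
        rng = np.random.default_rng(1)
        seqs = ["".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, 7)) for _ in range(40)]
        for s in seqs[:5]:
            d_self = fragment_distance(s, s, sim)
            assert all(fragment_distance(s, t, sim) >= d_self - 1e-12 for t in seqs)

    def test_length_mismatch_rejected(self, sim):
        with pytest.raises(ValueError):
            fragment_distance("KK", "KKK", sim)

    def test_distance_matrix_matches_scalar(self, sim):
        rng = np.random.default_rng(2)
        frags = random_fragments(15, rng, WindowSpec(3, 3))
        codes = code_matrix(frags)
        D = distance_matrix(codes, codes, sim)
        for i in range(15):
            for j in range(15):
                assert D[i, j] == pytest.approx(
                    fragment_distance(frags[i].residues, frags[j].residues, sim)
                )


def brute_force_knn_score(query, reference, k, sim):
    """Independent oracle: full sort over scalar distances with key tie-break."""
    usable = sorted(
        (f for f in reference if f.key != query.key),
        key=lambda f: (fragment_distance(query.residues, f.residues, sim), f.key),
    )
    return sum(f.label == "positive" for f in usable[:k]) / k


class TestKnnScore:
    def test_derived_two_residue_example(self, sim):
        # distances from query "KK": "KK" 0.4 < "AK" 0.6 < "CK" 0.667
        from acetylsite import SiteFragment

        window = WindowSpec(1, 0)
        def frag(res, pid, label="positive"):
            return SiteFragment(pid, 2, res, label, window=window)

        q = frag("KK", "q")
        refs = [frag("KK", "r1"), frag("AK", "r2"), frag("CK", "r3", "negative")]
        assert fragment_distance("KK", "KK", sim) == pytest.approx(0.4)
        assert fragment_distance("KK", "AK", sim) == pytest.approx(0.6)
        assert knn_score(q, refs, 1, sim) == 1.0
        assert knn_score(q, refs, 3, sim) == pytest.approx(2 / 3)

    def test_all_positive_reference(self, sim):
        rng = np.random.default_rng(3)
        refs = random_fragments(20, rng, p_positive=1.0)
        q = make_fragment("AAKAA", pid="query")
        assert all(knn_score(q, refs, k, sim) == 1.0 for k in (1, 5, 20))

    def test_self_exclusion_by_key(self, sim):
        rng = np.random.default_rng(4)
        refs = random_fragments(10, rng)
        q = refs[0]
        with pytest.raises(ValueError):
            knn_score(q, refs, 10, sim)  # only 9 usable after self-exclusion
        assert 0.0 <= knn_score(q, refs, 9, sim) <= 1.0

    def test_matches_brute_force_oracle(self, sim):
        rng = np.random.default_rng(5)
        refs = random_fragments(60, rng, WindowSpec(2, 2))
        queries = random_fragments(8, rng, WindowSpec(2, 2), prefix="q") + refs[:2]
        for q in queries:
            usable = sum(f.key != q.key for f in refs)
            for k in (1, 3, 10, usable):
                assert knn_score(q, refs, k, sim) == brute_force_knn_score(q, refs, k, sim)

    def test_vectorized_matrix_matches_scalar(self, sim):
        rng = np.random.default_rng(6)
        refs = random_fragments(50, rng, WindowSpec(2, 2))
        config = KnnConfig(k_fractions=(0.05, 0.2, 0.5))
        M = knn_score_matrix(refs[:10], refs, config, sim)
        for i, q in enumerate(refs[:10]):
            for j, k in enumerate(config.ks(49)):
                assert M[i, j] == pytest.approx(knn_score(q, refs, k, sim))


class TestKnnConfig:
    def test_round_half_up_schedule(self):
        config = KnnConfig()
        assert config.ks(10_000) == [3, 5, 10, 20, 40]  # 2.5 rounds up to 3
        assert config.ks(100)[0] == 1  # minimum_k floor

    def test_five_scores_by_default(self, sim):
        rng = np.random.default_rng(7)
        refs = random_fragments(30, rng)
        v = knn_feature_vector(make_fragment("AAKAA", pid="q"), refs, KnnConfig(), sim)
        assert v.shape == (5,) and ((0 <= v) & (v <= 1)).all()

    def test_fractions_must_increase(self):
        with pytest.raises(ValueError):
            KnnConfig(k_fractions=(0.2, 0.1))


class TestAssembledFeatures:
    def test_block_lengths(self, sim, janin):
        rng = np.random.default_rng(8)
        refs = random_fragments(30, rng, WindowSpec(10, 10))
        frag = refs[0]
        offsets = list(range(-8, 0)) + [1, 3, 4, 6, 7]  # 13 positions
        fv = assemble_features(frag, offsets, refs, sim, janin)
        assert fv.values.shape == (20 * 13 + 5 + 13,)
        assert fv.layout.span("BE") == slice(0, 260)
        assert fv.layout.span("KNN") == slice(260, 265)
        assert fv.layout.span("AASA") == slice(265, 278)

    def test_block_subsets(self, sim, janin):
        rng = np.random.default_rng(9)
        refs = random_fragments(20, rng, WindowSpec(10, 10))
        offsets = list(range(-8, 0)) + [1, 3, 4, 6, 7]
        be_only = assemble_features(refs[0], offsets, blocks=("BE",), sim=sim, index=janin)
        knn_only = assemble_features(refs[0], offsets, refs, sim, janin, blocks=("KNN",))
        assert be_only.values.shape == (260,)
        assert knn_only.values.shape == (5,)

    def test_unknown_block_rejected(self, sim):
        with pytest.raises(ValueError, match="unknown"):
            FeatureEncoder([1, 2], blocks=("BE", "PSSM"))

    def test_positive_knn_scores_exceed_negative_on_planted_data(self, planted_corpus, sim):
        corpus, _ = planted_corpus
        frags = list(corpus)
        enc = FeatureEncoder(
            [o for o in corpus.window.offsets if o != 0], blocks=("KNN",)
        )
        X = enc.encode_matrix(frags, reference=frags)
        labels = np.array([f.label == "positive" for f in frags])
        assert X[labels].mean() > X[~labels].mean()


class TestPropertyScreening:
    def test_informative_index_outranks_constant(self):
        spec = SyntheticDatasetSpec(
            n_positive=120, n_negative=120, seed=21,
            motif=MotifSpec(enriched={-2: "W"}, p_enrich=0.9),
            window=WindowSpec(3, 3),
        )
        corpus, _ = generate_fragments(spec)
        informative = PropertyIndex(
            "w-heavy", {aa: (1.0 if aa == "W" else 0.0) for aa in AMINO_ACIDS}
        )
        constant = PropertyIndex("flat", {aa: 0.5 for aa in AMINO_ACIDS})
        table = screen_property_indices(
            [constant, informative], list(corpus), corpus.labels
        )
        assert list(table["index_name"]) == ["w-heavy", "flat"]
        assert table["cv_accuracy"].iloc[0] > table["cv_accuracy"].iloc[1]
        assert table["cv_accuracy"].iloc[1] == pytest.approx(0.5, abs=0.1)

    def test_duplicate_names_rejected(self, planted_corpus):
        corpus, _ = planted_corpus
        ix = PropertyIndex("dup", {aa: 1.0 * i for i, aa in enumerate(AMINO_ACIDS)})
        with pytest.raises(ValueError, match="duplicate"):
            screen_property_indices([ix, ix], list(corpus), corpus.labels)
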