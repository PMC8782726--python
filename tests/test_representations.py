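import numpy as np
import pytest

from mitoscreen.chem_io import MoleculeRecord, standardize
from mitoscreen.errors import ConfigError, EmptyResultError
from mitoscreen.representations import (KIND_PHARM2D, KIND_SHAPE3D,
                                        Mol2vecEncoder, Pharm2DScheme,
                                        Shape3DScheme, SubstructureSentence,
                                        molecule_seed, pharm2d_fingerprint,
                                        sentence, shape3d_fingerprint)


def rec(smiles, rid="x"):
    return standardize(MoleculeRecord(id=rid, raw_smiles=smiles))


# --- substructure sentences --------------------------------------------------

@pytest.mark.parametrize("smiles, radius, n_tokens, n_distinct", [
    ("c1ccccc1", 1, 12, 2),   # all benzene atoms equivalent: one r0 + one r1 token
    ("C", 1, 2, 1),           # isolated atom: r1 padded from r0
    ("CCO", 0, 3, 3),         # three distinct r0 environments
])
def test_sentence_token_counts_and_distinct_environments(smiles, radius,
                                                         n_tokens, n_distinct):
    s = sentence(rec(smiles), radius)
    assert len(s.tokens) == n_tokens
    assert len(set(s.tokens)) == n_distinct


def test_sentence_deterministic_and_spelling_invariant():
    assert sentence(rec("OCC"), 1) == sentence(rec("CCO"), 1)
    assert sentence(rec("c1ccccc1"), 2) == sentence(rec("C1=CC=CC=C1"), 2)


def test_sentence_rejects_negative_radius():
    with pytest.raises(ConfigError):
        sentence(rec("CCO"), -1)


# --- embedding model ---------------------------------------------------------

def test_training_is_bit_reproducible(small_corpus):
    a = Mol2vecEncoder(vector_size=16, epochs=1, seed=3).fit(small_corpus)
    b = Mol2vecEncoder(vector_size=16, epochs=1, seed=3).fit(small_corpus)
    assert np.array_equal(a.vectors_, b.vectors_)
    assert a.vocabulary_ == b.vocabulary_


def test_vocabulary_bounded_by_distinct_tokens(small_corpus, small_encoder):
    distinct = set()
    for r in small_corpus:
        distinct.update(sentence(r, small_encoder.radius).tokens)
    assert len(small_encoder.vocabulary_) <= len(distinct)
    assert small_encoder.vectors_.shape == (len(small_encoder.vocabulary_),
                                            small_encoder.vector_size)


def test_min_count_above_all_frequencies_is_fatal(small_corpus):
    with pytest.raises(EmptyResultError, match="min_count"):
        Mol2vecEncoder(min_count=10 ** 6, epochs=1).fit(small_corpus[:3])


def test_embedding_is_sum_of_token_vectors(small_encoder):
    tok_a, tok_b = list(small_encoder.vocabulary_)[:2]
    va = small_encoder.vectors_[small_encoder.vocabulary_[tok_a]]
    vb = small_encoder.vectors_[small_encoder.vocabulary_[tok_b]]
    got = small_encoder.embed_sentence(SubstructureSentence((tok_a, tok_b))).values
    assert np.allclose(got, va + vb, atol=0)
    doubled = small_encoder.embed_sentence(SubstructureSentence((tok_a, tok_a))).values
    assert np.allclose(doubled, 2 * va, atol=1e-15)


def test_all_oov_sentence_embeds_to_zero(small_encoder):
    v = small_encoder.embed_sentence(SubstructureSentence(("nope", "also-nope")))
    assert v.dim == small_encoder.vector_size
    assert not v.values.any()


def test_model_serialization_round_trip(tmp_path, small_encoder):
    small_encoder.save(tmp_path / "model", card_lines=["test"])
    back = Mol2vecEncoder.load(tmp_path / "model")
    assert np.array_equal(back.vectors_, small_encoder.vectors_)
    assert back.vocabulary_ == small_encoder.vocabulary_
    assert back.counts_ == small_encoder.counts_


# --- 2D pharmacophore fingerprint -------------------------------------------

def test_pharm2d_benzene_has_aromatic_pair_and_is_deterministic():
    fp1 = pharm2d_fingerprint(rec("c1ccccc1"))
    fp2 = pharm2d_fingerprint(rec("c1ccccc1"))
    assert fp1.values == fp2.values and fp1.values
    assert all(0 <= i < fp1.dim for i in fp1.values)
    assert all(c > 0 for c in fp1.values.values())


def test_pharm2d_methane_is_empty():
    fp = pharm2d_fingerprint(rec("C"))
    assert fp.values == {} and fp.kind == KIND_PHARM2D


def test_pharm2d_indices_respect_fingerprint_size():
    fp = pharm2d_fingerprint(rec("NC(=O)c1ccc(O)cc1"), Pharm2DScheme(fingerprint_size=256))
    assert fp.dim == 256 and max(fp.values) < 256


# --- 3D feature-map fingerprint ---------------------------------------------

def test_shape3d_unit_norm_and_seed_determinism():
    a = shape3d_fingerprint(rec("c1ccccc1O"), seed=11)
    b = shape3d_fingerprint(rec("c1ccccc1O"), seed=11)
    assert a is not None
    assert np.isclose(np.linalg.norm(a.values), 1.0)
    assert np.array_equal(a.values, b.values)
    assert a.kind == KIND_SHAPE3D and a.dim == 48


def test_shape3d_single_conformer_matches_mean_of_identical():
    # a rigid ring: every conformer is the same up to noise, so the
    # aggregate over k conformers stays close to the single-conformer map
    one = shape3d_fingerprint(rec("c1ccccc1"), n_conf=1, seed=5)
    many = shape3d_fingerprint(rec("c1ccccc1"), n_conf=4, seed=5)
    assert np.allclose(one.values, many.values, atol=0.05)


def test_shape3d_featureless_molecule_is_missing_channel():
    assert shape3d_fingerprint(rec("C"), seed=1) is None


def test_molecule_seed_is_stable_and_31_bit():
    s = molecule_seed(42, "CMP001")
    assert s == molecule_seed(42, "CMP001")
    assert 0 <= s < 2 ** 31
    assert s != molecule_seed(42, "CMP002")
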