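import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitoscreen.config import ScreeningConfig
from mitoscreen.errors import ConfigError
from mitoscreen.representations import (KIND_EMBED1D, KIND_PHARM2D,
                                        RepresentationVector)
from mitoscreen.scoring import (SimilarityScore, aggregate_filtered,
                                best_reference_score, cosine_clamped,
                                hyperspace_filter, similarity, tanimoto)


def dense(v):
    v = np.asarray(v, dtype=float)
    return RepresentationVector(KIND_EMBED1D, v, v.size)


def sparse(bits):
    return RepresentationVector(KIND_PHARM2D, {b: 1 for b in bits}, 2048)


# --- similarity kernels ------------------------------------------------------

def test_similarity_examples():
    assert similarity(dense([1, 2, 3]), dense([1, 2, 3])) == pytest.approx(1.0, abs=1e-12)
    assert similarity(dense([1, 0]), dense([0, 1])) == 0.0
    assert similarity(sparse({1, 2, 3}), sparse({2, 3, 4})) == 0.5
    assert similarity(dense([1, 1]), dense([-1, -1])) == 0.0  # clamped cosine
    assert similarity(dense([0, 0]), dense([1, 1])) == 0.0    # zero vector -> 0
    assert similarity(sparse(set()), sparse({1})) == 0.0      # empty fp -> 0


def test_similarity_kind_mismatch_is_fatal():
    with pytest.raises(ConfigError):
        similarity(dense([1]), sparse({1}))


@given(st.sets(st.integers(0, 100), max_size=30),
       st.sets(st.integers(0, 100), max_size=30))
def test_tanimoto_matches_brute_force_set_arithmetic(a, b):
    expected = len(a & b) / len(a | b) if a and b else 0.0
    assert tanimoto(frozenset(a), frozenset(b)) == expected


@given(st.lists(st.floats(-5, 5), min_size=4, max_size=4),
       st.lists(st.floats(-5, 5), min_size=4, max_size=4))
def test_dense_similarity_symmetric_and_bounded(x, y):
    v, w = np.array(x), np.array(y)
    s = cosine_clamped(v, w)
    assert s == cosine_clamped(w, v)
    assert 0.0 <= s <= 1.0


# --- the hyper-space filter --------------------------------------------------

def piecewise_oracle(s, theta):
    if s == 1:
        return 0.0
    if theta <= s < 1:
        return s
    return 0.0


@pytest.mark.parametrize("theta", [0.5, 0.75, 0.9])
def test_filter_matches_piecewise_oracle_on_grid(theta):
    for s in np.round(np.arange(0, 1.0001, 0.01), 2):
        assert hyperspace_filter(float(s), theta) == piecewise_oracle(float(s), theta)


def test_filter_boundary_and_near_one_tolerance():
    assert hyperspace_filter(0.75, 0.75) == 0.75
    assert hyperspace_filter(1.0 - 1e-12, 0.75) == 0.0   # within the s=1 tolerance
    assert hyperspace_filter(1.0 - 1e-6, 0.75) == 1.0 - 1e-6


def test_filter_rejects_unnormalized_scores_and_bad_theta():
    with pytest.raises(ConfigError):
        hyperspace_filter(1.2, 0.75)
    with pytest.raises(ConfigError):
        hyperspace_filter(-0.2, 0.75)
    with pytest.raises(ConfigError):
        hyperspace_filter(0.5, 1.5)


# --- best-reference scoring --------------------------------------------------

def test_best_reference_matches_brute_force_maximum():
    rng = np.random.default_rng(0)
    refs = [dense(rng.random(8)) for _ in range(14)]
    comp = dense(rng.random(8))
    out = best_reference_score(
        "c1", {KIND_EMBED1D: comp, KIND_PHARM2D: None, "shape3d": None},
        {KIND_EMBED1D: refs, KIND_PHARM2D: [None] * 14, "shape3d": [None] * 14},
        [f"R{i:02d}" for i in range(14)])
    brute = [similarity(r, comp) for r in refs]
    assert out[KIND_EMBED1D].s_raw == max(brute)
    assert out[KIND_EMBED1D].reference_id == f"R{int(np.argmax(brute)):02d}"
    assert out[KIND_PHARM2D].s_raw is None   # missing channel stays missing


def test_best_reference_singleton_and_self_match():
    v = dense([1, 2, 3])
    out = best_reference_score("c", {KIND_EMBED1D: v, KIND_PHARM2D: None,
                                     "shape3d": None},
                               {KIND_EMBED1D: [v], KIND_PHARM2D: [None],
                                "shape3d": [None]}, ["R00"])
    assert out[KIND_EMBED1D].s_raw == pytest.approx(1.0, abs=1e-12)
    assert out[KIND_EMBED1D].reference_id == "R00"


# --- aggregation -------------------------------------------------------------

def _scores(s1, s2, s3):
    vals = {"embed1d": s1, "pharm2d": s2, "shape3d": s3}
    return {k: SimilarityScore("c", "r", k, v, 0.0) for k, v in vals.items()}


def test_aggregate_mean_of_equal_channels():
    cfg = ScreeningConfig()
    assert aggregate_filtered(_scores(0.8, 0.8, 0.8), cfg) == pytest.approx(0.8)


def test_aggregate_renormalizes_over_missing_channels():
    cfg = ScreeningConfig()
    assert aggregate_filtered(_scores(0.9, None, 0.8), cfg) == pytest.approx(0.85)


def test_aggregate_zeroes_exact_duplicates():
    cfg = ScreeningConfig()
    assert aggregate_filtered(_scores(1.0, 1.0, 1.0), cfg) == 0.0


def test_aggregate_min_rule_takes_worst_channel():
    cfg = ScreeningConfig(aggregate_rule="min")
    assert aggregate_filtered(_scores(0.9, 0.8, 0.85), cfg) == pytest.approx(0.8)


def test_aggregate_all_missing_returns_none():
    cfg = ScreeningConfig()
    assert aggregate_filtered(_scores(None, None, None), cfg) is None


# --- config validation -------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"theta": 0.0}, {"theta": 1.0},
    {"representation_weights": (0.5, 0.5, 0.5)},
    {"aggregate_rule": "median"},
    {"outlier_mad_k": -1.0},
    {"top_n": 0},
])
def test_config_validation_rejects_bad_values(kwargs):
    with pytest.raises(ConfigError):
        ScreeningConfig(**kwargs)
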