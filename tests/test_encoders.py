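"""One-hot and CKSAAP feature extraction against nested-loop references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abagnet.encoders import (
    EmbeddingMatrix,
    cksaap_classic,
    cksaap_fused,
    lookup_embeddings,
    one_hot_encode,
)
from abagnet.io_formats import ALPHABET, AA_INDEX, EmbeddingStore, SequenceRecord

RNG = np.random.default_rng(23)


def random_seq(i, length, with_x=False):
    letters = list(ALPHABET) + (["X"] * 4 if with_x else [])
    return SequenceRecord(f"s{i}", "".join(RNG.choice(letters, size=length)))


# ---------------------------------------------------------------------------
# Reference implementations (deliberately naive nested loops)

def cksaap_loop(residues: str, k: int) -> np.ndarray:
    out = np.zeros((k + 1, 20, 20))
    for g in range(k + 1):
        count = 0
        block = np.zeros((20, 20))
        for t in range(len(residues) - g - 1):
            a, b = residues[t], residues[t + g + 1]
            if a in AA_INDEX and b in AA_INDEX:
                block[AA_INDEX[a], AA_INDEX[b]] += 1
                count += 1
        if count:
            out[g] = block / count
    return out.reshape(-1)


def fused_loop(residues: str, E: np.ndarray, k: int) -> np.ndarray:
    D = E.shape[1]
    out = np.zeros((D, k + 1, 20, 20))
    for g in range(k + 1):
        count = 0
        acc = np.zeros((D, 20, 20))
        for t in range(len(residues) - g - 1):
            a, b = residues[t], residues[t + g + 1]
            if a in AA_INDEX and b in AA_INDEX:
                for d in range(D):
                    acc[d, AA_INDEX[a], AA_INDEX[b]] += 0.5 * (E[t, d]
                                                              + E[t + g + 1, d])
                count += 1
        if count:
            out[:, g] = acc / count
    return out


# ---------------------------------------------------------------------------
# One-hot

def test_one_hot_basics():
    m = one_hot_encode(SequenceRecord("a", "A")).values
    assert m.shape == (1, 20)
    assert m[0, 0] == 1 and m.sum() == 1


def test_one_hot_row_sums_and_mask():
    seq = SequenceRecord("a", "ACXW")
    m = one_hot_encode(seq).values
    np.testing.assert_array_equal(m.sum(axis=1), [1, 1, 0, 1])


def test_one_hot_column_sums_count_letters():
    seq = random_seq(0, 40)
    m = one_hot_encode(seq).values
    for j, aa in enumerate(ALPHABET):
        assert m[:, j].sum() == seq.residues.count(aa)


# ---------------------------------------------------------------------------
# Classic CKSAAP

def test_cksaap_single_window():
    v = cksaap_classic(SequenceRecord("a", "AC"), k=0)
    block = v.block(0)
    assert block[AA_INDEX["A"], AA_INDEX["C"]] == 1.0
    assert block.sum() == 1.0
    assert np.count_nonzero(block) == 1


def test_cksaap_vector_length_matches_dimension_formula():
    v = cksaap_classic(random_seq(0, 30), k=3)
    assert v.values.shape == ((3 + 1) * 20 * 20,)


def test_cksaap_matches_loop_oracle_on_100_random_sequences():
    for i in range(100):
        k = int(RNG.integers(0, 5))
        seq = random_seq(i, int(RNG.integers(10, 61)), with_x=(i % 3 == 0))
        np.testing.assert_array_equal(
            cksaap_classic(seq, k).values, cksaap_loop(seq.residues, k)
        )


def test_cksaap_block_sums_and_denominator_without_x():
    seq = random_seq(0, 37)
    k = 4
    v = cksaap_classic(seq, k)
    for g in range(k + 1):
        assert abs(v.block(g).sum() - 1.0) < 1e-12  # L - g - 1 valid windows


def test_cksaap_short_sequence_gives_zero_blocks():
    v = cksaap_classic(SequenceRecord("a", "AC"), k=3)
    assert v.block(0).sum() == 1.0
    for g in (1, 2, 3):
        assert v.block(g).sum() == 0.0


def test_cksaap_rejects_negative_k():
    with pytest.raises(ValueError):
        cksaap_classic(SequenceRecord("a", "ACD"), k=-1)


# ---------------------------------------------------------------------------
# Fused CKSAAP

def test_fused_reduces_to_classic_under_unit_embedding():
    for i in range(20):
        seq = random_seq(i, int(RNG.integers(8, 40)), with_x=(i % 2 == 0))
        k = int(RNG.integers(0, 4))
        emb = EmbeddingMatrix(seq.id, np.ones((len(seq), 1)))
        fused = cksaap_fused(seq, emb, k).values[0]
        classic = cksaap_classic(seq, k).values.reshape(k + 1, 20, 20)
        np.testing.assert_allclose(fused, classic, atol=1e-12)


def test_fused_matches_loop_oracle():
    seq = random_seq(0, 15)
    E = RNG.normal(size=(15, 2))
    got = cksaap_fused(seq, EmbeddingMatrix(seq.id, E), k=1).values
    np.testing.assert_allclose(got, fused_loop(seq.residues, E, 1), atol=1e-12)


def test_fused_shape_is_D_by_gaps_by_grid():
    seq = random_seq(0, 25)
    E = RNG.normal(size=(25, 6))
    out = cksaap_fused(seq, EmbeddingMatrix(seq.id, E), k=3)
    assert out.values.shape == (6, 4, 20, 20)


def test_fused_is_linear_in_the_embedding():
    seq = random_seq(0, 22)
    E1 = RNG.normal(size=(22, 3))
    E2 = RNG.normal(size=(22, 3))
    alpha, beta = 0.7, -1.3
    lhs = cksaap_fused(
        seq, EmbeddingMatrix(seq.id, alpha * E1 + beta * E2), 2
    ).values
    rhs = (alpha * cksaap_fused(seq, EmbeddingMatrix(seq.id, E1), 2).values
           + beta * cksaap_fused(seq, EmbeddingMatrix(seq.id, E2), 2).values)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_fused_ignores_embedding_content_at_x_positions():
    residues = "ACDEXWYK"
    seq = SequenceRecord("a", residues)
    E1 = RNG.normal(size=(8, 2))
    E2 = E1.copy()
    E2[4] = 999.0  # only the masked position differs
    out1 = cksaap_fused(seq, EmbeddingMatrix("a", E1), 2).values
    out2 = cksaap_fused(seq, EmbeddingMatrix("a", E2), 2).values
    np.testing.assert_array_equal(out1, out2)


def test_fused_rejects_row_mismatch():
    seq = SequenceRecord("a", "ACDE")
    with pytest.raises(ValueError, match="rows"):
        cksaap_fused(seq, EmbeddingMatrix("a", np.ones((3, 2))), 1)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.text(alphabet=ALPHABET + "X", min_size=2, max_size=40),
       st.integers(min_value=0, max_value=4))
def test_cksaap_property_identifier_invariance_and_oracle(residues, k):
    a = cksaap_classic(SequenceRecord("one", residues), k)
    b = cksaap_classic(SequenceRecord("two", residues), k)
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(a.values, cksaap_loop(residues, k))


# ---------------------------------------------------------------------------
# Store lookup

def test_lookup_embeddings_round_trip_and_errors():
    seq = SequenceRecord("a", "ACDEFGHIKL")
    store = EmbeddingStore({"a": RNG.normal(size=(10, 5))})
    emb = lookup_embeddings(store, seq)
    np.testing.assert_array_equal(emb.values, store["a"])
    with pytest.raises(KeyError, match="missing"):
        lookup_embeddings(store, SequenceRecord("missing", "ACD"))
    bad = EmbeddingStore({"a": RNG.normal(size=(9, 5))})
    with pytest.raises(ValueError, match="rows"):
        lookup_embeddings(bad, seq)
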