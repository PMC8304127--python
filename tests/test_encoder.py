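import numpy as np
import pytest

from reference_impl import scalar_attention, scalar_bilstm, scalar_lstm_gates
from riskattn.corpus import Post
from riskattn.encoder import (
    AttentionOutput,
    AttentionParams,
    EncoderState,
    LSTMParams,
    bilstm_encode,
    export_attention,
    lstm_step,
    read_attention,
    self_attention,
)


def _zero_params(D, H):
    z = lambda *s: np.zeros(s)
    return LSTMParams(
        W={g: z(D, H) for g in "fioc"}, V={g: z(H, H) for g in "fioc"}, b={g: z(H) for g in "fioc"}
    )


def test_lstm_step_zero_parameters_closed_form(rng):
    """With all parameters zero: every gate is 0.5, candidate 0, so h = c = 0."""
    D, H = 3, 4
    h, c = lstm_step(rng.standard_normal(D), np.zeros(H), np.zeros(H), _zero_params(D, H))
    assert np.allclose(h, 0.0) and np.allclose(c, 0.0)


def test_lstm_step_shape_mismatch(rng):
    params = LSTMParams.random(3, 4, rng)
    with pytest.raises(ValueError, match="shape mismatch"):
        lstm_step(rng.standard_normal(5), np.zeros(4), np.zeros(4), params)


def test_gate_and_hidden_state_bounds(rng):
    """Gates stay in (0,1) and hidden components in (-1,1) for 100 random draws."""
    for _ in range(100):
        D = int(rng.integers(1, 5))
        H = int(rng.integers(1, 5))
        params = LSTMParams.random(D, H, rng)
        x = rng.standard_normal(D) * 5
        h_prev = rng.uniform(-1, 1, H)
        c_prev = rng.standard_normal(H) * 3
        f, i, o, ct, c, h = scalar_lstm_gates(x, h_prev, c_prev, params)
        for gate in (f, i, o):
            assert all(0.0 < v < 1.0 for v in gate)
        h_vec, c_vec = lstm_step(x, h_prev, c_prev, params)
        np.testing.assert_allclose(h_vec, h, atol=1e-12)
        np.testing.assert_allclose(c_vec, c, atol=1e-12)
        assert (np.abs(h_vec) < 1.0).all()


def test_bilstm_matches_scalar_reference(rng):
    """Vectorized BiLSTM equals the scalar-loop recurrence to 1e-8 (N<=5, H<=4)."""
    for _ in range(10):
        N = int(rng.integers(1, 6))
        D = int(rng.integers(1, 5))
        H = int(rng.integers(1, 5))
        fwd = LSTMParams.random(D, H, rng)
        bwd = LSTMParams.random(D, H, rng)
        emb = rng.standard_normal((N, D))
        state = bilstm_encode(emb, np.ones(N, bool), fwd, bwd)
        ref = scalar_bilstm(emb.tolist(), fwd, bwd)
        np.testing.assert_allclose(state.hidden_states, np.array(ref), atol=1e-8)


def test_bilstm_single_token(rng):
    fwd = LSTMParams.random(3, 2, rng)
    bwd = LSTMParams.random(3, 2, rng)
    emb = rng.standard_normal((1, 3))
    state = bilstm_encode(emb, np.ones(1, bool), fwd, bwd)
    hf, _ = lstm_step(emb[0], np.zeros(2), np.zeros(2), fwd)
    hb, _ = lstm_step(emb[0], np.zeros(2), np.zeros(2), bwd)
    np.testing.assert_allclose(state.hidden_states[0], np.concatenate([hf, hb]), atol=1e-12)


def test_bilstm_reversal_symmetry(rng):
    """Swapping directions and reversing the input reverses and half-swaps the states."""
    N, D, H = 6, 3, 4
    fwd = LSTMParams.random(D, H, rng)
    bwd = LSTMParams.random(D, H, rng)
    emb = rng.standard_normal((N, D))
    orig = bilstm_encode(emb, np.ones(N, bool), fwd, bwd).hidden_states
    flipped = bilstm_encode(emb[::-1], np.ones(N, bool), bwd, fwd).hidden_states
    swapped = np.concatenate([flipped[::-1, H:], flipped[::-1, :H]], axis=1)
    np.testing.assert_allclose(orig, swapped, atol=1e-10)


def test_bilstm_padding_neutrality(rng):
    N, D, H = 4, 3, 2
    fwd = LSTMParams.random(D, H, rng)
    bwd = LSTMParams.random(D, H, rng)
    emb = rng.standard_normal((N, D))
    base = bilstm_encode(emb, np.ones(N, bool), fwd, bwd)
    padded_emb = np.vstack([emb, rng.standard_normal((2, D))])
    mask = np.array([True] * N + [False] * 2)
    padded = bilstm_encode(padded_emb, mask, fwd, bwd)
    np.testing.assert_allclose(padded.hidden_states[:N], base.hidden_states, atol=1e-12)
    assert np.allclose(padded.hidden_states[N:], 0.0)


def test_bilstm_all_masked_errors(rng):
    fwd = LSTMParams.random(2, 2, rng)
    with pytest.raises(ValueError):
        bilstm_encode(rng.standard_normal((3, 2)), np.zeros(3, bool), fwd, fwd)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def _rand_state(rng, N, H2, mask=None):
    hs = rng.standard_normal((N, H2)) * 0.9
    mask = np.ones(N, bool) if mask is None else mask
    hs[~mask] = 0.0
    return EncoderState(hidden_states=hs, mask=mask)


def test_attention_matches_scalar_reference(rng):
    for _ in range(10):
        N = int(rng.integers(1, 6))
        H2 = int(rng.integers(2, 7))
        A = int(rng.integers(1, 5))
        params = AttentionParams.random(H2, A, rng)
        state = _rand_state(rng, N, H2)
        out = self_attention(state, params)
        alpha_ref, sent_ref = scalar_attention(
            state.hidden_states.tolist(), params.W.tolist(), params.b.tolist(), params.u.tolist()
        )
        np.testing.assert_allclose(out.weights, alpha_ref, atol=1e-10)
        np.testing.assert_allclose(out.sentence_vector, sent_ref, atol=1e-10)
        # explicit weighted-sum recomputation
        np.testing.assert_allclose(
            out.sentence_vector, out.weights @ state.hidden_states, atol=1e-10
        )


def test_attention_identical_states_uniform(rng):
    params = AttentionParams.random(4, 3, rng)
    hs = np.tile(rng.standard_normal(4), (5, 1))
    out = self_attention(EncoderState(hidden_states=hs, mask=np.ones(5, bool)), params)
    np.testing.assert_allclose(out.weights, 0.2, atol=1e-12)


def test_attention_single_position(rng):
    params = AttentionParams.random(4, 3, rng)
    mask = np.array([False, True, False])
    state = _rand_state(rng, 3, 4, mask)
    out = self_attention(state, params)
    np.testing.assert_allclose(out.weights, [0.0, 1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(out.sentence_vector, state.hidden_states[1], atol=1e-12)


def test_attention_normalization_and_convexity(rng):
    """Weights sum to 1, vanish on masked positions; sentence vector lies in the
    componentwise hull of the unmasked states (convex combination)."""
    for _ in range(50):
        N = int(rng.integers(2, 9))
        H2 = int(rng.integers(2, 7))
        mask = rng.random(N) < 0.7
        if not mask.any():
            mask[0] = True
        params = AttentionParams.random(H2, 3, rng)
        state = _rand_state(rng, N, H2, mask)
        out = self_attention(state, params)
        assert out.weights[~mask].sum() == 0.0
        assert abs(out.weights.sum() - 1.0) < 1e-6
        sub = state.hidden_states[mask]
        assert (out.sentence_vector >= sub.min(axis=0) - 1e-12).all()
        assert (out.sentence_vector <= sub.max(axis=0) + 1e-12).all()


def test_encoder_is_order_sensitive(rng):
    """Unlike the count features, the encoder changes when token order changes."""
    D, H = 3, 4
    fwd = LSTMParams.random(D, H, rng)
    bwd = LSTMParams.random(D, H, rng)
    params = AttentionParams.random(2 * H, 3, rng)
    emb = rng.standard_normal((5, D))
    perm = emb[[2, 0, 4, 1, 3]]
    s1 = self_attention(bilstm_encode(emb, np.ones(5, bool), fwd, bwd), params).sentence_vector
    s2 = self_attention(bilstm_encode(perm, np.ones(5, bool), fwd, bwd), params).sentence_vector
    assert not np.allclose(s1, s2)


# ---------------------------------------------------------------------------
# attention export
# ---------------------------------------------------------------------------


def test_export_attention_roundtrip(tmp_path):
    post = Post(post_id="p1", raw_text="one two three four", risk_label="b")
    out = AttentionOutput(weights=np.array([0.25, 0.25, 0.25, 0.25]), sentence_vector=np.zeros(2))
    path = tmp_path / "attn.tsv"
    export_attention(post, out, path)
    tokens, weights = read_attention(path)
    assert tokens == post.tokens
    np.testing.assert_allclose(weights, out.weights, atol=1e-9)
    assert abs(weights.sum() - 1.0) < 1e-6
    html = (tmp_path / "attn.tsv.html").read_text()
    assert "three" in html and "rgba" in html


def test_export_attention_length_mismatch(tmp_path):
    post = Post(post_id="p1", raw_text="one two three", risk_label="b")
    out = AttentionOutput(weights=np.array([0.5, 0.5]), sentence_vector=np.zeros(2))
    with pytest.raises(ValueError, match="tokens"):
        export_attention(post, out, tmp_path / "attn.tsv")
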