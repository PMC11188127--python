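"""Architecture contracts: attention oracle, cell/U-net behavior,
initialization, equivariance, parameter accounting."""

import numpy as np
import pytest

import stackdenoise._autodiff as ad
from stackdenoise.errors import ConfigError
from stackdenoise.model import (
    ModelConfig,
    conv_project_kqv,
    cell_forward,
    extract_cell_tensors,
    forward,
    forward_var,
    frame_attention,
    init_model,
    param_shapes,
    parameter_count,
)

RNG = np.random.default_rng(99)


# ---------------------------------------------------------------------------
# init


def test_init_deterministic(tiny_model_config):
    a = init_model(tiny_model_config, 3)
    b = init_model(tiny_model_config, 3)
    for name in a.tensors:
        np.testing.assert_array_equal(a.tensors[name], b.tensors[name])


def test_init_seed_changes_weights(tiny_model_config):
    a = init_model(tiny_model_config, 3)
    b = init_model(tiny_model_config, 4)
    assert any(not np.array_equal(a.tensors[n], b.tensors[n]) for n in a.tensors)


def test_identity_at_initialization(tiny_model_config):
    params = init_model(tiny_model_config, 0)
    x = RNG.normal(size=(1, 1, 3, 16, 16))
    np.testing.assert_array_equal(forward(params, x), x)


def test_invalid_config_divisibility():
    with pytest.raises(ConfigError, match="divisible"):
        ModelConfig(base_channels=6, n_heads=4).validate()


def test_zero_base_channels_rejected():
    with pytest.raises(ConfigError):
        ModelConfig(base_channels=0).validate()


def test_even_kernel_rejected():
    with pytest.raises(ConfigError):
        ModelConfig(proj_kernel=4).validate()


# ---------------------------------------------------------------------------
# K/Q/V projection


def _random_cell(c=4, cfg=None, seed=0):
    cfg = cfg or ModelConfig(in_channels=1, base_channels=c, n_down_levels=1,
                             cells_per_level=1, n_heads=2)
    params = init_model(cfg, seed)
    return cfg, extract_cell_tensors(params, "down0.cell0")


def test_kqv_identity_kernel_is_identity():
    _, cell = _random_cell()
    c = cell["k.w"].shape[0]
    ident = np.zeros_like(cell["k.w"])
    for i in range(c):
        ident[i, i, 1, 1] = 1.0
    cell = dict(cell, **{"k.w": ident, "k.b": np.zeros(c)})
    x = RNG.normal(size=(1, c, 3, 6, 6))
    k, _, _ = conv_project_kqv(x, cell)
    np.testing.assert_allclose(k, x, atol=1e-12)


def test_kqv_zero_input_zero_output():
    _, cell = _random_cell()
    x = np.zeros((1, 4, 2, 5, 5))
    k, q, v = conv_project_kqv(x, cell)
    for t in (k, q, v):
        np.testing.assert_array_equal(t, np.zeros_like(x))


def test_kqv_per_frame_permutation():
    _, cell = _random_cell()
    x = RNG.normal(size=(1, 4, 5, 6, 6))
    perm = RNG.permutation(5)
    base = conv_project_kqv(x, cell)
    permuted = conv_project_kqv(x[:, :, perm], cell)
    for t0, t1 in zip(base, permuted):
        np.testing.assert_allclose(t1, t0[:, :, perm], atol=1e-12)


def test_kqv_preserves_channels():
    _, cell = _random_cell()
    x = RNG.normal(size=(2, 4, 3, 8, 8))
    for t in conv_project_kqv(x, cell):
        assert t.shape == x.shape


# ---------------------------------------------------------------------------
# frame attention


def test_attention_single_frame_passthrough():
    k, q, v = (RNG.normal(size=(1, 4, 1, 5, 5)) for _ in range(3))
    out, scores = frame_attention(k, q, v, n_heads=2, return_scores=True)
    np.testing.assert_allclose(out, v, atol=1e-12)
    np.testing.assert_allclose(scores, 1.0)


def test_attention_zero_query_uniform_mean():
    k = RNG.normal(size=(1, 4, 5, 3, 3))
    v = RNG.normal(size=(1, 4, 5, 3, 3))
    out = frame_attention(k, np.zeros_like(k), v, n_heads=2)
    expected = np.broadcast_to(v.mean(axis=2, keepdims=True), v.shape)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_attention_bruteforce_oracle_enumerable():
    """B=1, F=2, 1 head, 1x1 frames: compare against an explicit softmax."""
    k = np.array([0.3, -1.2])
    q = np.array([0.7, 0.4])
    v = np.array([2.0, -3.0])
    K = k.reshape(1, 1, 2, 1, 1)
    Q = q.reshape(1, 1, 2, 1, 1)
    V = v.reshape(1, 1, 2, 1, 1)
    out, scores = frame_attention(K, Q, V, n_heads=1, return_scores=True)
    # independent brute force: score[t,s] = q_t * k_s / sqrt(1*1*1)
    raw = np.array([[q[t] * k[s] for s in range(2)] for t in range(2)])
    e = np.exp(raw - raw.max(axis=1, keepdims=True))
    a = e / e.sum(axis=1, keepdims=True)
    expected = a @ v
    np.testing.assert_allclose(out.reshape(2), expected, atol=1e-10)
    np.testing.assert_allclose(scores.reshape(2, 2), a, atol=1e-10)


def test_attention_bruteforce_oracle_pooled_general():
    """Random small tensors vs a loop-based pooled-score computation."""
    b, c, f, h, w = 2, 4, 3, 2, 2
    nh, dh = 2, 2
    K, Q, V = (RNG.normal(size=(b, c, f, h, w)) for _ in range(3))
    out = frame_attention(K, Q, V, n_heads=nh)
    expected = np.empty_like(V)
    scale = 1.0 / np.sqrt(dh * h * w)
    for bi in range(b):
        for hd in range(nh):
            ch = slice(hd * dh, (hd + 1) * dh)
            raw = np.zeros((f, f))
            for t in range(f):
                for s in range(f):
                    raw[t, s] = np.sum(Q[bi, ch, t] * K[bi, ch, s]) * scale
            e = np.exp(raw - raw.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            for t in range(f):
                expected[bi, ch, t] = sum(a[t, s] * V[bi, ch, s] for s in range(f))
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_attention_rows_sum_to_one_and_score_shape():
    b, c, f = 2, 8, 5
    K, Q, V = (RNG.normal(size=(b, c, f, 4, 4)) * 3 for _ in range(3))
    _, scores = frame_attention(K, Q, V, n_heads=4, return_scores=True)
    assert scores.shape == (b, 4, f, f)  # F x F per head, never (HW) x (HW)
    np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_pixelwise_mode_shape_and_rows():
    b, c, f, h, w = 1, 4, 3, 2, 2
    K, Q, V = (RNG.normal(size=(b, c, f, h, w)) for _ in range(3))
    out, scores = frame_attention(K, Q, V, n_heads=2, mode="pixelwise", return_scores=True)
    assert out.shape == V.shape
    assert scores.shape == (b, 2, h * w, f, f)
    np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_head_mismatch_raises():
    K = RNG.normal(size=(1, 6, 2, 3, 3))
    with pytest.raises(ConfigError):
        frame_attention(K, K, K, n_heads=4)


# ---------------------------------------------------------------------------
# cell


def test_cell_zeroed_sublayers_reduce_to_projection():
    cfg, cell = _random_cell()
    for name in ("attn_out.w", "attn_out.b", "mix2.w", "mix2.b"):
        cell[name] = np.zeros_like(cell[name])
    x = RNG.normal(size=(1, 4, 3, 8, 8))
    out = cell_forward(x, cell, cfg)
    # residual structure: only the input projection remains
    proj = conv_project_kqv(x, {"k.w": cell["proj.w"], "k.b": cell["proj.b"],
                                "q.w": cell["proj.w"], "q.b": cell["proj.b"],
                                "v.w": cell["proj.w"], "v.b": cell["proj.b"]})[0]
    np.testing.assert_allclose(out, proj, atol=1e-10)


def test_cell_shape_contract():
    cfg, cell = _random_cell()
    x = RNG.normal(size=(2, 4, 3, 10, 12))
    assert cell_forward(x, cell, cfg).shape == x.shape


def test_cell_frame_permutation_equivariance():
    cfg, cell = _random_cell(seed=2)
    x = RNG.normal(size=(1, 4, 6, 8, 8))
    perm = RNG.permutation(6)
    base = cell_forward(x, cell, cfg)
    permuted = cell_forward(x[:, :, perm], cell, cfg)
    np.testing.assert_allclose(permuted, base[:, :, perm], atol=1e-10)


# ---------------------------------------------------------------------------
# full network


def _random_params(cfg, seed=0):
    """init_model weights but with a non-zero post-conv (generic weights)."""
    params = init_model(cfg, seed)
    rng = np.random.default_rng(seed + 1)
    for name in ("post.w", "post.b"):
        params.tensors[name] = rng.normal(0, 0.05, size=params.tensors[name].shape)
    return params


@pytest.mark.parametrize("f,h,w", [(1, 32, 32), (3, 34, 30), (8, 64, 64), (2, 9, 13)])
def test_unet_output_shape_matches_input(tiny_model_config, f, h, w):
    params = _random_params(tiny_model_config)
    x = RNG.normal(size=(1, 1, f, h, w))
    assert forward(params, x).shape == x.shape


def test_unet_frame_permutation_equivariance(tiny_model_config):
    params = _random_params(tiny_model_config, seed=5)
    x = RNG.normal(size=(1, 1, 5, 16, 16))
    perm = RNG.permutation(5)
    base = forward(params, x)
    permuted = forward(params, x[:, :, perm])
    np.testing.assert_allclose(permuted, base[:, :, perm], atol=1e-9)


def test_unet_rejects_nonfinite_input(tiny_model_config):
    params = init_model(tiny_model_config, 0)
    x = np.zeros((1, 1, 2, 16, 16))
    x[0, 0, 0, 0, 0] = np.inf
    from stackdenoise.errors import NumericError

    with pytest.raises(NumericError):
        forward(params, x)


def test_unet_wrong_channel_count(tiny_model_config):
    params = init_model(tiny_model_config, 0)
    with pytest.raises(ConfigError):
        forward(params, np.zeros((1, 2, 2, 16, 16)))


def test_gradient_reaches_every_parameter(tiny_model_config):
    params = _random_params(tiny_model_config, seed=7)
    pv = {n: ad.leaf(t) for n, t in params.tensors.items()}
    x = ad.const(RNG.normal(size=(1, 1, 3, 16, 16)))
    out = forward_var(params, x, trainable_pv=pv)
    ad.backward(ad.vmean(ad.mul(out, out)))
    dead = [n for n, v in pv.items() if v.grad is None or not np.any(v.grad)]
    assert dead == []


# ---------------------------------------------------------------------------
# parameter accounting


def _hand_count(cfg: ModelConfig) -> int:
    """Independent layer-by-layer count: conv = k^2*cin*cout + cout,
    norm affine = 2c per norm, walking the declared architecture."""
    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    def cell(c):
        total = conv(c, c, cfg.proj_kernel)  # input projection
        total += 4 * conv(c, c, cfg.proj_kernel)  # k, q, v, attention output
        total += 2 * 2 * c  # two instance norms, gamma + beta
        total += conv(c, cfg.mixer_expansion * c, cfg.mixer_kernel)
        total += conv(cfg.mixer_expansion * c, c, cfg.mixer_kernel)
        return total

    total = conv(cfg.in_channels, cfg.base_channels, cfg.proj_kernel)  # pre
    c = cfg.base_channels
    for _ in range(cfg.n_down_levels):
        total += cfg.cells_per_level * cell(c)
        total += conv(c, 2 * c, cfg.proj_kernel)  # downsample
        c *= 2
    for _ in range(cfg.n_down_levels):
        total += conv(c, c // 2, cfg.proj_kernel)  # upsample conv
        total += conv(c, c // 2, cfg.proj_kernel)  # merge after concat
        c //= 2
        total += cfg.cells_per_level * cell(c)
    total += conv(cfg.base_channels, cfg.in_channels, cfg.proj_kernel)  # post
    return total


@pytest.mark.parametrize("cfg", [
    ModelConfig(in_channels=1, base_channels=8, n_down_levels=2, cells_per_level=1, n_heads=2),
    ModelConfig(in_channels=2, base_channels=4, n_down_levels=1, cells_per_level=2,
                n_heads=2, proj_kernel=5, mixer_kernel=3, mixer_expansion=3),
])
def test_parameter_count_matches_hand_count(cfg):
    assert parameter_count(cfg) == _hand_count(cfg)


def test_parameter_count_matches_init_tensors(tiny_model_config):
    params = init_model(tiny_model_config, 0)
    assert parameter_count(tiny_model_config) == sum(t.size for t in params.tensors.values())


def test_doubling_cells_doubles_cell_parameters():
    base = ModelConfig(in_channels=1, base_channels=8, n_down_levels=2, cells_per_level=1, n_heads=2)
    double = ModelConfig(in_channels=1, base_channels=8, n_down_levels=2, cells_per_level=2, n_heads=2)
    fixed = sum(
        int(np.prod(s)) for n, s in param_shapes(base).items()
        if ".cell" not in n
    )
    cells_base = parameter_count(base) - fixed
    cells_double = parameter_count(double) - fixed
    assert cells_double == 2 * cells_base
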