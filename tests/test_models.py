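"""Model construction, attention variants and parameter accounting."""

import numpy as np
import pytest

from slicevit.models import (
    ViTConfig,
    build_model,
    canonical_config,
    class_attention_forward,
    count_trainable_parameters,
    expected_parameter_count,
    params_report,
    reattention,
    solve_width_config,
)
from slicevit.nn import cross_entropy

PUBLISHED_COUNTS = {
    "vit_vanilla": 53_532_675,
    "vit_224_8": 40_949_763,
    "ovitad": 38_406_147,
    "deepvit": 53_532_867,
    "cait": 120_707_075,
}


def tiny(variant="ovitad", **kw):
    base = dict(variant=variant, image_size=56, patch_size=14, embed_dim=32,
                depth=2, heads=4, head_dim=8, mlp_dim=16, num_classes=3,
                dropout=0.0, emb_dropout=0.0)
    base.update(kw)
    return ViTConfig(**base)


# -- configuration contracts -------------------------------------------------

def test_indivisible_patch_size_rejected():
    with pytest.raises(ValueError, match="divisible"):
        ViTConfig(variant="vanilla", image_size=56, patch_size=9)


def test_token_arithmetic():
    cfg = ViTConfig(variant="ovitad", image_size=56, patch_size=8, heads=8)
    assert cfg.num_patches == 49
    assert cfg.num_tokens == 50


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        ViTConfig(variant="resnet", image_size=224, patch_size=32)


# -- parameter accounting ----------------------------------------------------

@pytest.mark.parametrize("name,target", sorted(PUBLISHED_COUNTS.items()))
def test_published_parameter_counts(name, target):
    assert expected_parameter_count(canonical_config(name)) == target


def test_built_ovitad_count_matches_published():
    model = build_model(canonical_config("ovitad"))
    assert count_trainable_parameters(model) == PUBLISHED_COUNTS["ovitad"]


@pytest.mark.parametrize("variant,extra", [
    ("vanilla", {}),
    ("ovitad", {}),
    ("deepvit", {}),
    ("deepvit", {"reattn_theta_trainable": True}),
    ("cait", {"cait_cls_depth": 2}),
])
def test_count_dual_route(variant, extra):
    """Built-model count equals the closed-form count (independent routes)."""
    cfg = tiny(variant, **extra)
    assert count_trainable_parameters(build_model(cfg)) == expected_parameter_count(cfg)


def test_count_is_pure_function_of_config():
    cfg = tiny()
    a = count_trainable_parameters(build_model(cfg, seed=0))
    b = count_trainable_parameters(build_model(cfg, seed=99))
    assert a == b


def test_head_halving_difference_law():
    """vanilla minus 8-head twin == depth * 2 * embed * (16-8) * head_dim."""
    v = expected_parameter_count(canonical_config("vit_vanilla"))
    v8 = expected_parameter_count(canonical_config("vit_224_8"))
    assert v - v8 == 6 * 2 * 1024 * (16 - 8) * 64 * 2  # qkv(3x) + out proj = 4x
    # the published delta itself
    assert v - v8 == 12_582_912


def test_affine_map_count():
    from slicevit.nn import Linear

    lin = Linear(10, 5, bias=True)
    assert sum(p.data.size for p in lin.parameters()) == 55


def test_params_report_lists_all_five():
    rows = params_report()
    assert [r["model"] for r in rows] == ["CaIT", "DeepViT", "ViT-vanilla",
                                          "ViT-224-8", "OViTAD"]
    assert [r["params"] for r in rows] == [120_707_075, 53_532_867, 53_532_675,
                                           40_949_763, 38_406_147]


# -- config solver -----------------------------------------------------------

def test_solver_recovers_known_config():
    cfg = canonical_config("ovitad")
    target = expected_parameter_count(cfg)
    hits = solve_width_config(target, {"variant": "ovitad", "image_size": 56,
                                       "depth": 6, "heads": 8, "num_classes": 3})
    assert any(h.patch_size == 14 and h.embed_dim == 1024 and h.head_dim == 64
               for h in hits)


def test_solver_no_solution():
    assert solve_width_config(1, {"variant": "vanilla", "image_size": 224,
                                  "depth": 6, "heads": 16, "num_classes": 3}) == []


def test_solver_head_reduction_arithmetic():
    """The two 224-input targets differ by 6 x 2,097,152, i.e. halving the
    heads at embed 1024 / head width 64 (arithmetic oracle)."""
    delta = PUBLISHED_COUNTS["vit_vanilla"] - PUBLISHED_COUNTS["vit_224_8"]
    assert delta == 6 * 2_097_152
    assert 2_097_152 == 4 * 1024 * 8 * 64  # qkv + out-proj columns of 8 heads


def test_solver_deepvit_stretch_target():
    hits = solve_width_config(PUBLISHED_COUNTS["deepvit"],
                              {"variant": "deepvit", "image_size": 224,
                               "depth": 6, "heads": 16, "num_classes": 3})
    assert any(not h.reattn_theta_trainable for h in hits)


# -- forward contracts -------------------------------------------------------

@pytest.mark.parametrize("variant,extra", [
    ("vanilla", {}), ("ovitad", {}), ("deepvit", {}),
    ("cait", {"cait_cls_depth": 1}),
])
def test_logits_shape(variant, extra, rng):
    model = build_model(tiny(variant, **extra))
    x = rng.random((2, 3, 56, 56))
    assert model.forward(x).logits.shape == (2, 3)


def test_attention_rows_sum_to_one(rng):
    model = build_model(tiny())
    x = rng.random((2, 3, 56, 56))
    stack = model.forward(x, collect_attention=True).attention
    assert stack.maps.shape == (2, 4, 17, 17)
    assert np.allclose(stack.maps.sum(axis=-1), 1.0, atol=1e-5)


def test_eval_forward_deterministic(rng):
    model = build_model(tiny())
    x = rng.random((2, 3, 56, 56))
    a = model.forward(x).logits.data
    b = model.forward(x).logits.data
    assert np.array_equal(a, b)


def test_gradient_flows_to_every_trainable_tensor(rng):
    """One-step fit on a 2-image batch leaves no dead parameters."""
    model = build_model(tiny("deepvit", reattn_theta_trainable=True))
    x = rng.random((2, 3, 56, 56))
    y = np.array([0, 2])
    loss = cross_entropy(model.forward(x, train=True,
                                       rng=np.random.default_rng(0)).logits, y)
    loss.backward()
    for name, p in model.named_parameters():
        if not p.trainable:
            continue
        assert p.grad is not None, name
        assert np.any(p.grad != 0), name


def test_wrong_input_size_rejected(rng):
    model = build_model(tiny())
    with pytest.raises(ValueError, match="expected input"):
        model.forward(rng.random((1, 3, 48, 48)))


# -- re-attention ------------------------------------------------------------

def test_reattention_identity_theta(rng):
    maps = rng.random((2, 3, 3))
    maps /= maps.sum(-1, keepdims=True)
    assert np.allclose(reattention(maps, np.eye(2)), maps)


def test_reattention_permutation_theta(rng):
    """Permutation theta permutes heads (brute-force 2-head, 3-token check)."""
    maps = rng.random((2, 3, 3))
    perm = np.array([[0.0, 1.0], [1.0, 0.0]])
    mixed = reattention(maps, perm)
    # independent brute force: out[g] = sum_h theta[h, g] * maps[h]
    expected = np.zeros_like(maps)
    for g in range(2):
        for h in range(2):
            expected[g] += perm[h, g] * maps[h]
    assert np.allclose(mixed, expected)
    assert np.allclose(mixed[0], maps[1])
    assert np.allclose(mixed[1], maps[0])


def test_reattention_preserves_shape_and_checks_dims(rng):
    maps = rng.random((4, 5, 5))
    assert reattention(maps, np.eye(4)).shape == (4, 5, 5)
    with pytest.raises(ValueError, match="theta"):
        reattention(maps, np.eye(3))


# -- class attention ---------------------------------------------------------

def test_class_attention_leaves_patches_untouched(rng):
    model = build_model(tiny("cait", cait_cls_depth=1))
    x = rng.random((2, 3, 56, 56))
    block = model.cls_blocks[0]
    tokens = rng.normal(size=(2, 16, 32))
    cls = rng.normal(size=(2, 1, 32))
    from slicevit.nn import Tensor, cat

    full = cat([Tensor(cls), Tensor(tokens)], axis=1)
    out = block(full, None, None)
    assert np.array_equal(out.data[:, 1:, :], tokens)
    assert not np.allclose(out.data[:, 0, :], cls[:, 0, :])


def test_class_attention_weights_sum_to_one(rng):
    model = build_model(tiny("cait", cait_cls_depth=1))
    x = rng.random((1, 3, 56, 56))
    stack = model.forward(x, collect_attention=True).attention
    cls_map = stack.maps[-1]  # last recorded layer is the class-attention one
    assert np.allclose(cls_map.sum(axis=-1), 1.0, atol=1e-5)


def test_class_attention_single_token_oracle():
    """Hand-computed linear-algebra oracle on a 1-patch-token instance."""
    cfg = tiny("cait", cait_cls_depth=1, image_size=14, patch_size=14,
               embed_dim=8, heads=1, head_dim=8, mlp_dim=4)
    model = build_model(cfg, seed=11)
    block = model.cls_blocks[0]
    rng = np.random.default_rng(2)
    patch = rng.normal(size=(1, 1, 8))
    cls = rng.normal(size=(1, 1, 8))
    got = class_attention_forward(block, patch, cls)

    # independent oracle: pre-norm, joint qkv, query from cls only,
    # softmax over {cls, patch}, value mix, out-projection, residual,
    # then the block's MLP sublayer on the class token alone.
    def ln(v, g, b, eps=1e-5):
        mu, var = v.mean(), v.var()
        return (v - mu) / np.sqrt(var + eps) * g + b

    x = np.concatenate([cls, patch], axis=1)[0]
    normed = np.stack([ln(row, block.norm1.gamma.data, block.norm1.beta.data)
                       for row in x])
    qkv = normed @ block.attn.to_qkv.weight.data
    q, k, v = qkv[:, :8], qkv[:, 8:16], qkv[:, 16:]
    scores = (q[0] @ k.T) / np.sqrt(8)
    w = np.exp(scores - scores.max())
    w /= w.sum()
    attn_out = (w @ v) @ block.attn.to_out.weight.data + block.attn.to_out.bias.data
    cls1 = x[0] + attn_out
    normed2 = ln(cls1, block.norm2.gamma.data, block.norm2.beta.data)
    h = normed2 @ block.mlp.fc1.weight.data + block.mlp.fc1.bias.data
    h = 0.5 * h * (1 + np.tanh(np.sqrt(2 / np.pi) * (h + 0.044715 * h**3)))
    expected = cls1 + h @ block.mlp.fc2.weight.data + block.mlp.fc2.bias.data
    assert np.allclose(got[0, 0], expected, atol=1e-10)


def test_class_attention_requires_cait_block():
    model = build_model(tiny())
    with pytest.raises(TypeError, match="cait"):
        class_attention_forward(model.blocks[0], np.zeros((1, 1, 32)),
                                np.zeros((1, 1, 32)))
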