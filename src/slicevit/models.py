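"""Vision-transformer variants with exact trainable-parameter accounting.

Five classifiers are built from one configuration type:

``vit_vanilla``   224-pixel input, 16 self-attention heads, depth 6
``vit_224_8``     as vanilla but 8 heads
``deepvit``       vanilla plus re-attention (head-mixing) blocks
``cait``          12 self-attention layers + 2 class-attention layers
``ovitad``        reduced 56-pixel (fMRI) / 112-pixel (sMRI) input, 8 heads

All variants share the same solved internals: patch embedding as a
bias-free linear projection, a fixed 2-D sine/cosine positional
embedding, a learnable class token, pre-norm encoder blocks whose
query/key/value projections carry no bias, a 2048-wide feed-forward
sublayer, and a LayerNorm + linear classification head. These choices
are pinned by the exact published parameter counts (see
``expected_parameter_count`` and ``solve_width_config``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import numpy as np

from .nn import Dropout, LayerNorm, Linear, Module, Parameter, Tensor, cat

__all__ = [
    "ViTConfig",
    "AttentionStack",
    "VisionTransformer",
    "build_model",
    "canonical_config",
    "count_trainable_parameters",
    "expected_parameter_count",
    "reattention",
    "class_attention_forward",
    "solve_width_config",
    "params_report",
    "CANONICAL_VARIANTS",
]

VARIANTS = ("vanilla", "deepvit", "cait", "ovitad")


@dataclass(frozen=True)
class ViTConfig:
    """Complete architectural description of one transformer variant."""

    variant: str
    image_size: int
    patch_size: int
    embed_dim: int = 1024
    depth: int = 6
    heads: int = 16
    head_dim: int = 64
    mlp_dim: int = 2048
    num_classes: int = 3
    channels: int = 3
    dropout: float = 0.1
    emb_dropout: float = 0.1
    cait_cls_depth: int = 0
    reattn_theta_trainable: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.depth < 1 or self.heads < 1:
            raise ValueError("depth and heads must be >= 1")
        for name in ("embed_dim", "head_dim", "mlp_dim", "num_classes", "channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.variant == "cait" and self.cait_cls_depth < 1:
            raise ValueError("cait requires cait_cls_depth >= 1")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size**2

    @property
    def num_tokens(self) -> int:
        return self.num_patches + 1

    @property
    def inner_dim(self) -> int:
        return self.heads * self.head_dim

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ViTConfig":
        return cls(**d)


#: the canonical (solved) configurations reproducing the published counts
CANONICAL_VARIANTS = ("cait", "deepvit", "vit_vanilla", "vit_224_8", "ovitad")

_CANONICAL = {
    "vit_vanilla": dict(variant="vanilla", image_size=224, patch_size=32, heads=16),
    "vit_224_8": dict(variant="vanilla", image_size=224, patch_size=32, heads=8),
    "deepvit": dict(variant="deepvit", image_size=224, patch_size=32, heads=16),
    "cait": dict(variant="cait", image_size=224, patch_size=32, heads=16,
                 depth=12, cait_cls_depth=2),
    "ovitad": dict(variant="ovitad", image_size=56, patch_size=14, heads=8),
    "ovitad_smri": dict(variant="ovitad", image_size=112, patch_size=28, heads=8),
}

_DISPLAY_NAMES = {
    "cait": "CaIT",
    "deepvit": "DeepViT",
    "vit_vanilla": "ViT-vanilla",
    "vit_224_8": "ViT-224-8",
    "ovitad": "OViTAD",
    "ovitad_smri": "OViTAD-sMRI",
}


def canonical_config(name: str, num_classes: int = 3, **overrides) -> ViTConfig:
    """Return one of the five solved configurations by its model name."""
    if name not in _CANONICAL:
        raise ValueError(f"unknown canonical model {name!r}; choose from {sorted(_CANONICAL)}")
    kw = dict(_CANONICAL[name])
    kw["num_classes"] = num_classes
    kw.update(overrides)
    return ViTConfig(**kw)


# ---------------------------------------------------------------------------
# attention internals
# ---------------------------------------------------------------------------

@dataclass
class AttentionStack:
    """depth x heads grid of post-softmax attention maps for one image."""

    maps: np.ndarray  # (depth, heads, n, n)

    def __post_init__(self):
        if self.maps.ndim != 4:
            raise ValueError("attention stack must be depth x heads x n x n")
        rows = self.maps.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")
        if (self.maps < -1e-12).any():
            raise ValueError("attention entries must be nonnegative")

    @property
    def depth(self) -> int:
        return self.maps.shape[0]

    @property
    def heads(self) -> int:
        return self.maps.shape[1]


def reattention(head_scores: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Mix post-softmax attention maps across heads.

    ``out[g] = sum_h theta[h, g] * head_scores[h]`` — the head axis is
    multiplied by the transposed mixing matrix. The caller is expected to
    renormalize (the deepvit blocks use a LayerNorm over the head axis)
    before the maps are applied to values.
    """
    head_scores = np.asarray(head_scores)
    theta = np.asarray(theta)
    h = head_scores.shape[-3]
    if theta.shape != (h, h):
        raise ValueError(f"theta must be {h}x{h}, got {theta.shape}")
    return np.einsum("...hij,hg->...gij", head_scores, theta)


def posemb_sincos_2d(grid: int, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2-D sine/cosine positional embedding over a square patch grid."""
    if dim % 4 != 0:
        raise ValueError("embed_dim must be divisible by 4 for sincos embedding")
    y, x = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    omega = np.arange(dim // 4, dtype=np.float64) / max(dim / 4 - 1, 1)
    omega = 1.0 / (temperature**omega)
    y = y.reshape(-1, 1) * omega
    x = x.reshape(-1, 1) * omega
    return np.concatenate([np.sin(x), np.cos(x), np.sin(y), np.cos(y)], axis=1)


class _Attention(Module):
    """Multi-head self-attention; optionally deepvit re-attention."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator, reattn: bool = False):
        self.heads = cfg.heads
        self.head_dim = cfg.head_dim
        self.scale = cfg.head_dim**-0.5
        self.to_qkv = Linear(cfg.embed_dim, 3 * cfg.inner_dim, bias=False, rng=rng)
        self.to_out = Linear(cfg.inner_dim, cfg.embed_dim, bias=True, rng=rng)
        self.drop = Dropout(cfg.dropout)
        self.reattn = reattn
        if reattn:
            # identity mixing when frozen reproduces the published count;
            # the flag makes theta a trainable free matrix instead
            self.theta = Parameter(np.eye(cfg.heads), trainable=cfg.reattn_theta_trainable)
            self.reattn_gamma = Parameter(np.ones(cfg.heads))
            self.reattn_beta = Parameter(np.zeros(cfg.heads))

    def __call__(self, x: Tensor, rng, record: list | None) -> Tensor:
        b, n, _ = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.to_qkv(x)  # (b, n, 3*h*hd)
        qkv = qkv.reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (b, h, n, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        attn = scores.softmax(axis=-1)
        if record is not None:
            record.append(attn.data.copy())
        if self.reattn:
            mixed = attn.transpose(0, 2, 3, 1) @ self.theta  # (b, i, j, h)
            mixed = mixed.layer_norm(self.reattn_gamma, self.reattn_beta)
            attn = mixed.transpose(0, 3, 1, 2)
        attn = self.drop(attn, rng)
        out = attn @ v  # (b, h, n, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, h * hd)
        return self.to_out(out)


class _ClassAttention(Module):
    """Attention in which only the class token emits a query (cait)."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator):
        self.heads = cfg.heads
        self.head_dim = cfg.head_dim
        self.scale = cfg.head_dim**-0.5
        self.to_qkv = Linear(cfg.embed_dim, 3 * cfg.inner_dim, bias=False, rng=rng)
        self.to_out = Linear(cfg.inner_dim, cfg.embed_dim, bias=True, rng=rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, rng, record: list | None) -> Tensor:
        """``x`` is (b, n, d) with the class token at index 0; returns the
        class-token update (b, 1, d). Patch tokens are not updated."""
        b, n, _ = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.to_qkv(x)
        qkv = qkv.reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        q_cls = q[:, :, 0:1, :]  # (b, h, 1, hd)
        scores = (q_cls @ k.transpose(0, 1, 3, 2)) * self.scale
        attn = scores.softmax(axis=-1)  # (b, h, 1, n)
        if record is not None:
            record.append(attn.data.copy())
        attn = self.drop(attn, rng)
        out = attn @ v  # (b, h, 1, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, 1, h * hd)
        return self.to_out(out)


class _FeedForward(Module):
    def __init__(self, cfg: ViTConfig, rng: np.random.Generator):
        self.fc1 = Linear(cfg.embed_dim, cfg.mlp_dim, bias=True, rng=rng)
        self.fc2 = Linear(cfg.mlp_dim, cfg.embed_dim, bias=True, rng=rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, rng) -> Tensor:
        return self.drop(self.fc2(self.drop(self.fc1(x).gelu(), rng)), rng)


class _Block(Module):
    """Pre-norm encoder block: x + attn(LN(x)); x + mlp(LN(x))."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator,
                 attention_cls=_Attention, **attn_kw):
        self.norm1 = LayerNorm(cfg.embed_dim)
        self.attn = attention_cls(cfg, rng, **attn_kw)
        self.norm2 = LayerNorm(cfg.embed_dim)
        self.mlp = _FeedForward(cfg, rng)

    def __call__(self, x: Tensor, rng, record) -> Tensor:
        x = x + self.attn(self.norm1(x), rng, record)
        return x + self.mlp(self.norm2(x), rng)


class _ClassBlock(_Block):
    """Class-attention block: only the class token is updated."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator):
        super().__init__(cfg, rng, attention_cls=_ClassAttention)

    def __call__(self, x: Tensor, rng, record) -> Tensor:
        cls_update = self.attn(self.norm1(x), rng, record)
        patches = x[:, 1:, :]
        cls = x[:, 0:1, :] + cls_update
        cls = cls + self.mlp(self.norm2(cls), rng)
        return cat([cls, patches], axis=1)


@dataclass
class ForwardResult:
    logits: Tensor
    features: np.ndarray  # final class-token embedding, (b, embed_dim)
    attention: AttentionStack | None = None


class VisionTransformer(Module):
    """Patch-embedding transformer classifier (all variants)."""

    def __init__(self, config: ViTConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        cfg = config
        patch_dim = cfg.channels * cfg.patch_size**2
        self.patch_embed = Linear(patch_dim, cfg.embed_dim, bias=False, rng=rng)
        self.cls_token = Parameter(rng.normal(0, 0.02, size=(1, 1, cfg.embed_dim)))
        self._posemb = posemb_sincos_2d(cfg.grid_size, cfg.embed_dim)  # fixed buffer
        self.emb_drop = Dropout(cfg.emb_dropout)
        if cfg.variant == "cait":
            self.blocks = [_Block(cfg, rng) for _ in range(cfg.depth)]
            self.cls_blocks = [_ClassBlock(cfg, rng) for _ in range(cfg.cait_cls_depth)]
        else:
            reattn = cfg.variant == "deepvit"
            self.blocks = [_Block(cfg, rng, reattn=reattn) for _ in range(cfg.depth)]
            self.cls_blocks = []
        self.norm = LayerNorm(cfg.embed_dim)
        self.head = Linear(cfg.embed_dim, cfg.num_classes, bias=True, rng=rng)

    # -- input handling ----------------------------------------------------
    def patchify(self, images: np.ndarray) -> np.ndarray:
        """(b, c, H, W) -> (b, N, c*p*p) flattened patches."""
        cfg = self.config
        b, c, hh, ww = images.shape
        if c != cfg.channels or hh != cfg.image_size or ww != cfg.image_size:
            raise ValueError(
                f"expected input {cfg.channels}x{cfg.image_size}x{cfg.image_size}, "
                f"got {c}x{hh}x{ww}"
            )
        p, g = cfg.patch_size, cfg.grid_size
        x = images.reshape(b, c, g, p, g, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # b, gy, gx, c, p, p
        return x.reshape(b, g * g, c * p * p)

    # -- forward -----------------------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                collect_attention: bool = False) -> ForwardResult:
        """Classify a batch of images.

        ``train=True`` enables dropout (``rng`` then required); evaluation
        mode is deterministic.
        """
        if train and rng is None:
            raise ValueError("training-mode forward requires an rng for dropout")
        drop_rng = rng if train else None
        b = images.shape[0]
        cfg = self.config

        tokens = Tensor(self.patchify(np.asarray(images, dtype=np.float64)))
        x = self.patch_embed(tokens) + Tensor(self._posemb)
        cls = self.cls_token.broadcast_to((b, 1, cfg.embed_dim))
        record: list | None = [] if collect_attention else None

        if cfg.variant == "cait":
            # class token is inserted only after the self-attention stage
            x = self.emb_drop(x, drop_rng)
            for block in self.blocks:
                x = block(x, drop_rng, record)
            x = cat([cls, x], axis=1)
            for block in self.cls_blocks:
                x = block(x, drop_rng, record)
        else:
            x = cat([cls, x], axis=1)
            x = self.emb_drop(x, drop_rng)
            for block in self.blocks:
                x = block(x, drop_rng, record)

        x = self.norm(x)
        feat = x[:, 0, :]
        logits = self.head(feat)

        attention = None
        if collect_attention:
            n = cfg.num_tokens
            maps = np.stack([_embed_map(m[0], n) for m in record])
            attention = AttentionStack(maps=maps)
        return ForwardResult(logits=logits, features=feat.data.copy(), attention=attention)

    __call__ = forward


def _embed_map(m: np.ndarray, n: int) -> np.ndarray:
    """Embed a recorded (heads, rows, cols) attention map into a uniform
    (heads, n, n) grid; rows without a query (class token during cait
    self-attention, patch tokens during class attention) are identity."""
    heads, rows, cols = m.shape
    if rows == n and cols == n:
        return m
    full = np.tile(np.eye(n), (heads, 1, 1))
    if rows == 1:                # class-attention: only token 0 queries
        full[:, 0, :cols] = m[:, 0, :]
        if cols < n:             # renormalize is not needed; rows already sum to 1
            full[:, 0, cols:] = 0.0
    else:                        # patch-only self-attention: shift past cls
        full[:, 1:rows + 1, 1:cols + 1] = m
        full[:, 1:rows + 1, 0] = 0.0
    return full


def class_attention_forward(block: _ClassBlock, patch_tokens: np.ndarray,
                            cls_token: np.ndarray) -> np.ndarray:
    """Run one class-attention block; returns the updated class token.

    ``patch_tokens`` is (b, N, d) and ``cls_token`` (b, 1, d). Patch
    tokens are read-only for this stage.
    """
    if not isinstance(block, _ClassBlock):
        raise TypeError("class attention is only defined for cait class blocks")
    x = cat([Tensor(np.asarray(cls_token, dtype=np.float64)),
             Tensor(np.asarray(patch_tokens, dtype=np.float64))], axis=1)
    out = block(x, None, None)
    return out.data[:, 0:1, :]


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def count_trainable_parameters(model: Module) -> int:
    """Exact number of independently learnable scalar weights."""
    return int(sum(p.data.size for p in model.parameters() if p.trainable))


def expected_parameter_count(cfg: ViTConfig) -> int:
    """Closed-form trainable-parameter count for ``cfg`` (audit route)."""
    d, inner, mlp = cfg.embed_dim, cfg.inner_dim, cfg.mlp_dim
    per_layer = 4 * d                    # two pre-norm LayerNorms
    per_layer += d * 3 * inner           # qkv, no bias
    per_layer += inner * d + d           # output projection + bias
    per_layer += d * mlp + mlp + mlp * d + d
    n_layers = cfg.depth + (cfg.cait_cls_depth if cfg.variant == "cait" else 0)
    total = n_layers * per_layer
    if cfg.variant == "deepvit":
        total += cfg.depth * 2 * cfg.heads  # LayerNorm over the head axis
        if cfg.reattn_theta_trainable:
            total += cfg.depth * cfg.heads**2
    total += cfg.channels * cfg.patch_size**2 * d  # patch embedding, no bias
    total += d                                     # class token
    total += 2 * d + d * cfg.num_classes + cfg.num_classes  # final LN + head
    return int(total)


def build_model(config: ViTConfig, seed: int = 0) -> VisionTransformer:
    return VisionTransformer(config, rng=np.random.default_rng(seed))


_DEFAULT_SPACE = {
    "patch_size": (7, 8, 14, 16, 28, 32, 56),
    "embed_dim": (512, 768, 1024),
    "head_dim": (32, 64, 128),
    "mlp_dim": (2048,),
    "reattn_theta_trainable": (False, True),
}


def solve_width_config(target_count: int, fixed: ViTConfig | dict,
                       search_space: dict | None = None) -> list[ViTConfig]:
    """Enumerate free architectural fields and return every configuration
    whose exact parameter count equals ``target_count`` (empty list means
    no solution)."""
    space = dict(_DEFAULT_SPACE)
    if search_space:
        space.update(search_space)
    base = fixed.to_dict() if isinstance(fixed, ViTConfig) else dict(fixed)
    free = {k: v for k, v in space.items() if k not in base}
    hits: list[ViTConfig] = []
    keys = list(free)
    for combo in itertools.product(*(free[k] for k in keys)):
        kw = dict(base)
        kw.update(zip(keys, combo))
        try:
            cfg = ViTConfig(**kw)
        except (ValueError, TypeError):
            continue
        if expected_parameter_count(cfg) == target_count:
            hits.append(cfg)
    return hits


def params_report(num_classes: int = 3) -> "list[dict]":
    """Published-style parameter table for the five canonical variants."""
    rows = []
    for name in CANONICAL_VARIANTS:
        cfg = canonical_config(name, num_classes=num_classes)
        rows.append({
            "model": _DISPLAY_NAMES[name],
            "input": f"{cfg.channels},{cfg.image_size},{cfg.image_size}",
            "params": expected_parameter_count(cfg),
        })
    return rows
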