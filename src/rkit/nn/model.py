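"""A compact sequence/pair-track network for RNA.

The architecture mirrors the modern pair-track transformer recipe for RNA
chemical-mapping prediction: an embedding projects one-hot nucleotides into
a sequence track; a pairwise track is spawned from projected outer products
of a downsampled sequence representation plus relative-position encodings
clipped at +/- 8; each block then runs 1D convolution and pair-biased
self-attention on the sequence track, and outer-product-mean plus
triangular multiplicative updates (outgoing and incoming) on the pair
track.  Task heads: per-position reactivity channels (2A3/DMS), multi
-channel degradation, a positive scalar read-count (dropout) head, and a
pairwise secondary-structure head.

Desk-scale by design: a few thousand parameters, trainable to overfit small
synthetic sets on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..structure import SecondaryStructure
from .autodiff import Tensor, bce_with_logits
from .layers import (
    Conv1d,
    LayerNorm,
    Linear,
    Module,
    OuterProductMean,
    PairBiasedSelfAttention,
    TriangularUpdate,
)

__all__ = ["NetConfig", "ForwardOutput", "PairTrackNet", "flip_augment", "ss_loss"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
HEADS = ("reactivity", "degradation", "dropout", "secondary_structure")


@dataclass
class NetConfig:
    d_seq: int = 32
    d_pair: int = 8
    n_blocks: int = 2
    n_heads: int = 4
    conv_kernel: int = 5
    rel_pos_clip: int = 8
    downsample_rank: int = 4   # rank of the outer-product factors
    n_channels: int = 2        # reactivity: 2 (2A3, DMS); degradation: per task
    head: str = "reactivity"
    seed: int = 0
    learning_rate: float = 3e-3

    def __post_init__(self):
        if self.d_seq % self.n_heads:
            raise ValueError("d_seq must be divisible by n_heads")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")
        if self.rel_pos_clip < 1:
            raise ValueError("rel_pos_clip must be >= 1")
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")


@dataclass
class ForwardOutput:
    per_position: np.ndarray | None = None  # (L, C)
    pair_logits: np.ndarray | None = None   # (L, L)
    scalar: float | None = None             # dropout head, > 0


def one_hot(seq: str) -> np.ndarray:
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError as err:
        raise ValueError(f"invalid nucleotide {err.args[0]!r}") from None
    oh = np.zeros((len(seq), 4))
    oh[np.arange(len(seq)), idx] = 1.0
    return oh


class _Block(Module):
    def __init__(self, cfg: NetConfig, rng):
        self.norm_seq = LayerNorm(cfg.d_seq)
        self.conv = Conv1d(cfg.d_seq, cfg.d_seq, cfg.conv_kernel, rng)
        self.attn = PairBiasedSelfAttention(cfg.d_seq, cfg.d_pair, cfg.n_heads, rng)
        self.norm_pair = LayerNorm(cfg.d_pair)
        self.opm = OuterProductMean(cfg.d_seq, cfg.d_pair, cfg.downsample_rank, rng)
        self.tri_out = TriangularUpdate(cfg.d_pair, "outgoing", rng)
        self.tri_in = TriangularUpdate(cfg.d_pair, "incoming", rng)

    def __call__(self, x: Tensor, pair: Tensor) -> tuple[Tensor, Tensor]:
        x = x + self.conv(self.norm_seq(x)).relu()
        x = x + self.attn(x, pair)
        pair = pair + self.opm(x)
        pair = pair + self.tri_out(self.norm_pair(pair))
        pair = pair + self.tri_in(self.norm_pair(pair))
        return x, pair


class PairTrackNet(Module):
    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.embed = Linear(4, cfg.d_seq, rng)
        self.downsample = Linear(cfg.d_seq, cfg.downsample_rank, rng)
        self.spawn = Linear(cfg.downsample_rank * cfg.downsample_rank, cfg.d_pair, rng)
        # one shared embedding per clipped offset in [-clip, clip]
        self.rel_pos = Tensor(
            rng.normal(0.0, 0.1, size=(2 * cfg.rel_pos_clip + 1, cfg.d_pair)),
            requires_grad=True,
        )
        self.blocks = [_Block(cfg, rng) for _ in range(cfg.n_blocks)]
        self.head_reactivity = Linear(cfg.d_seq, cfg.n_channels, rng)
        self.head_dropout = Linear(cfg.d_seq, 1, rng)
        self.head_pair = Linear(cfg.d_pair, 1, rng)

    # -- track construction ------------------------------------------------
    def _tracks(self, batch_oh: np.ndarray) -> tuple[Tensor, Tensor]:
        B, L, _ = batch_oh.shape
        x = self.embed(Tensor(batch_oh))
        ds = self.downsample(x)
        r = self.config.downsample_rank
        a = ds.reshape(B, L, 1, r, 1)
        b = ds.reshape(B, 1, L, 1, r)
        pair = self.spawn((a * b).reshape(B, L, L, r * r))
        clip = self.config.rel_pos_clip
        offsets = np.arange(L)[None, :] - np.arange(L)[:, None]
        idx = np.clip(offsets, -clip, clip) + clip
        pair = pair + self.rel_pos[idx]
        for block in self.blocks:
            x, pair = block(x, pair)
        return x, pair

    def forward_batch(self, sequences: list[str]) -> dict[str, Tensor]:
        """Run a batch of equal-length sequences; returns track tensors and
        head outputs as autodiff tensors (for training)."""
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("batched sequences must share one length")
        batch_oh = np.stack([one_hot(s) for s in sequences])
        x, pair = self._tracks(batch_oh)
        out: dict[str, Tensor] = {"seq_track": x, "pair_track": pair}
        head = self.config.head
        if head in ("reactivity", "degradation"):
            out["per_position"] = self.head_reactivity(x)  # (B, L, C)
        elif head == "dropout":
            per_pos = self.head_dropout(x)  # (B, L, 1)
            out["scalar"] = per_pos.mean(axis=1).reshape(-1).exp()  # (B,), positive
        else:
            logits = self.head_pair(pair).reshape(*pair.shape[:3])  # (B, L, L)
            sym = (logits + logits.transpose(0, 2, 1)) * 0.5
            out["pair_logits"] = sym
        return out

    # -- checkpoints -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize config + weights to a portable .npz checkpoint."""
        import json
        from dataclasses import asdict

        arrays = {f"param_{k}": p.data for k, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "PairTrackNet":
        import json

        with np.load(path, allow_pickle=False) as ckpt:
            config = NetConfig(**json.loads(str(ckpt["config"])))
            net = cls(config)
            params = net.parameters()
            for k, p in enumerate(params):
                saved = ckpt[f"param_{k}"]
                if saved.shape != p.data.shape:
                    raise ValueError("checkpoint/architecture shape mismatch")
                p.data = saved
        return net

    def forward(self, seq: str) -> ForwardOutput:
        """Single-sequence inference returning plain numpy outputs."""
        if not seq:
            raise ValueError("empty sequence")
        out = self.forward_batch([seq])
        result = ForwardOutput()
        if "per_position" in out:
            result.per_position = out["per_position"].data[0]
        if "scalar" in out:
            result.scalar = float(out["scalar"].data[0])
        if "pair_logits" in out:
            result.pair_logits = out["pair_logits"].data[0]
        return result


def flip_augment(seq: str, labels: np.ndarray) -> tuple[str, np.ndarray]:
    """Reverse a sequence 3'-to-5' together with its per-position labels (no
    complementation) — the standard reactivity-data augmentation."""
    labels = np.asarray(labels)
    if labels.shape[0] != len(seq):
        raise ValueError("label length must match sequence length")
    return seq[::-1], labels[::-1].copy()


def ss_loss(
    pair_logits: Tensor | np.ndarray,
    target: SecondaryStructure,
    length_weighting: bool = True,
) -> Tensor:
    """Binary cross entropy between pair logits and the 0/1 connectivity
    matrix.  Positive cells are up-weighted by 2 (positives are sparse);
    with length weighting the per-sequence loss scales by L^2 so long
    structures contribute proportionally to their information content."""
    logits = pair_logits if isinstance(pair_logits, Tensor) else Tensor(pair_logits)
    if logits.ndim == 3:
        if logits.shape[0] != 1:
            raise ValueError("ss_loss expects a single structure's logits")
        logits = logits.reshape(*logits.shape[1:])
    L = target.length
    if logits.shape != (L, L):
        raise ValueError("logits/structure shape mismatch")
    m = target.pair_matrix()
    weights = np.where(m > 0, 2.0, 1.0)
    loss = bce_with_logits(logits, m, weights)
    if length_weighting:
        loss = loss * float(L * L)
    return loss
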