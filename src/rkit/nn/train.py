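"""Adam optimizer and desk-scale overfitting demos.

These training loops exist to show the architecture learns: they overfit a
small synthetic set (clipped-MAE objective for the reactivity head,
connectivity BCE for the structure head) and return the per-epoch loss
trace.  Deterministic given the config seed on a single thread.
"""

from __future__ import annotations

import numpy as np

from ..structure import SecondaryStructure
from .autodiff import Tensor, clip_ste
from .model import NetConfig, PairTrackNet, flip_augment, ss_loss

__all__ = ["Adam", "TrainingDivergence", "train_overfit_demo"]


class TrainingDivergence(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clipped_mae_loss(pred: Tensor, labels: np.ndarray) -> Tensor:
    """Mean absolute error after clipping predictions and data to [0, 1]
    (straight-through gradient for the prediction clip)."""
    target = np.clip(np.asarray(labels, dtype=float), 0.0, 1.0)
    return (clip_ste(pred, 0.0, 1.0) - target).abs().mean()


def train_overfit_demo(
    dataset: list[tuple[str, object]],
    config: NetConfig,
    epochs: int = 300,
    batch_size: int = 0,
    flip_augmentation: bool = False,
) -> tuple[PairTrackNet, list[float]]:
    """Train a fresh network to overfit a small synthetic dataset.

    ``dataset`` holds (sequence, labels) with labels an (L, C) reactivity
    matrix for the reactivity head or a :class:`SecondaryStructure` for the
    secondary-structure head.  Sequences must share one length for the
    reactivity head (they are trained as one batch).  Returns the trained
    network and the per-epoch mean training loss; raises
    :class:`TrainingDivergence` on NaN/inf loss.
    """
    if len(dataset) > 200:
        raise ValueError("overfit demo is desk-scale: at most 200 sequences")
    if any(len(seq) > 60 for seq, _ in dataset):
        raise ValueError("overfit demo is desk-scale: sequences up to 60 nt")
    net = PairTrackNet(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    trace: list[float] = []

    def anneal(epoch: int):
        # cosine-annealed learning rate; MAE's constant-magnitude gradients
        # otherwise leave Adam oscillating at a floor set by the step size
        opt.lr = config.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / max(epochs, 1)))

    if config.head == "reactivity":
        if flip_augmentation:
            # train on each example in both reading directions
            dataset = list(dataset) + [flip_augment(s, np.asarray(l)) for s, l in dataset]
        seqs = [s for s, _ in dataset]
        labels = np.stack([np.asarray(lab, dtype=float) for _, lab in dataset])
        n = len(seqs)
        bs = batch_size or min(n, 10)
        for epoch in range(epochs):
            anneal(epoch)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                out = net.forward_batch(seqs[start : start + bs])
                loss = _clipped_mae_loss(
                    out["per_position"], labels[start : start + bs]
                )
                if not np.isfinite(loss.data):
                    raise TrainingDivergence(epoch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * min(bs, n - start)
            trace.append(epoch_loss / n)
    elif config.head == "secondary_structure":
        for epoch in range(epochs):
            anneal(epoch)
            epoch_loss = 0.0
            for seq, target in dataset:
                if not isinstance(target, SecondaryStructure):
                    raise TypeError("structure head expects SecondaryStructure labels")
                out = net.forward_batch([seq])
                loss = ss_loss(out["pair_logits"], target)
                if not np.isfinite(loss.data):
                    raise TrainingDivergence(epoch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) / (target.length**2)
            trace.append(epoch_loss / len(dataset))
    else:
        raise ValueError("demo supports the reactivity and secondary_structure heads")
    return net, trace
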