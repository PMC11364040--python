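"""Self-supervised training: the Cref-matching loss on half-map patches.

Each training sample is a pair of half-map patches. The network input is
their average (the full-dataset patch, with noise reduced by sqrt(2));
the loss drives the FSC between input and network output toward the
Cref curve computed from the pair's own half-map FSC — no clean target
volume is ever needed. Optimization uses Adam with a staircase
exponential learning-rate schedule (multiply by ``decay`` every
``decay_every`` epochs). After each epoch the mean training loss, an
optional held-out evaluation loss, and the learning rate are recorded,
and a checkpoint may be written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fourier_shell import (
    build_shell_partition,
    cref_loss,
    cref_loss_with_grad,
)
from .grid import VolumeGrid
from .nn import Adam
from .patch_pipeline import PatchPair
from .unet_model import Denoiser, DenoiserConfig, build_denoiser, save_checkpoint

__all__ = ["TrainConfig", "TrainHistory", "lr_at_epoch", "train_denoiser"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings.

    Defaults are the full-scale training configuration: Adam
    (beta1=0.9, beta2=0.999, epsilon=1e-8), initial learning rate 3e-4
    decayed by 0.7 every 10 epochs, 195 epochs, batch size 6. Smoke-scale
    runs override epochs/batch and may raise the learning rate.
    ``select_best`` returns the checkpoint with the lowest evaluation
    loss instead of the final epoch; it is off by default because the
    model is not tuned on held-out data.
    """

    lr0: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.7
    decay_every: int = 10
    epochs: int = 195
    batch: int = 6
    seed: int = 0
    device: str = "cpu"
    checkpoint_every: int = 1
    select_best: bool = False

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or self.epsilon <= 0:
            raise ValueError("learning rate and epsilon must be positive")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")
        if self.decay_every < 1 or self.epochs < 1 or self.batch < 1:
            raise ValueError("decay_every, epochs and batch must be >= 1")
        if self.device != "cpu":
            raise ValueError(
                f"only the cpu backend is available, got device={self.device!r}"
            )


@dataclass
class TrainHistory:
    """Per-epoch loss, learning-rate and checkpoint records."""

    train_loss: list[float] = field(default_factory=list)
    eval_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    checkpoint_paths: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "eval_loss": self.eval_loss,
                "lr": self.lr,
            }
        ).to_csv(path, sep="\t", index=False)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Staircase schedule: ``lr0 * decay ** floor(epoch / decay_every)``."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return cfg.lr0 * cfg.decay ** (epoch // cfg.decay_every)


def _pair_loss(
    model: Denoiser, pair: PatchPair, partition, with_grad: bool
) -> float:
    mean_arr = pair.mean.astype(np.float32)
    vmean = VolumeGrid(mean_arr, voxel_size=pair.voxel_size)
    v1 = VolumeGrid(pair.p1, voxel_size=pair.voxel_size)
    v2 = VolumeGrid(pair.p2, voxel_size=pair.voxel_size)
    out = model.forward(mean_arr[None], train=with_grad)
    vout = VolumeGrid(out[0], voxel_size=pair.voxel_size)
    if with_grad:
        loss, grad = cref_loss_with_grad(vmean, vout, v1, v2, partition)
        model.backward(grad.astype(np.float32)[None])
        return loss
    return cref_loss(vmean, vout, v1, v2, partition)


def train_denoiser(
    dataset: list[PatchPair],
    dcfg: DenoiserConfig,
    tcfg: TrainConfig,
    eval_dataset: list[PatchPair] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Denoiser, TrainHistory]:
    """Train a denoiser on a patch-pair collection.

    Per step, the batch loss is the mean over patches of the Cref loss
    evaluated on (mean patch, model output, half-patches); gradients are
    averaged over the batch and applied with the scheduled learning
    rate. Shuffling, initialization and hence the whole loss history are
    deterministic for fixed seeds. Checkpoints are written to ``out_dir``
    every ``checkpoint_every`` epochs; the returned model carries the
    final-epoch weights (or the best-evaluation weights when
    ``select_best`` and an evaluation set are given).
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    edges = {p.edge for p in dataset}
    if len(edges) != 1:
        raise ValueError(f"patches must share one edge, got {sorted(edges)}")
    edge = edges.pop()
    if edge % 2**dcfg.depth:
        raise ValueError(
            f"patch edge {edge} is not a multiple of 2^depth = {2**dcfg.depth}"
        )
    voxel = dataset[0].voxel_size
    partition = build_shell_partition((edge, edge, edge), voxel)
    model = build_denoiser(dcfg)
    optimizer = Adam(
        model.parameters(), beta1=tcfg.beta1, beta2=tcfg.beta2, epsilon=tcfg.epsilon
    )
    rng = np.random.default_rng(tcfg.seed)
    history = TrainHistory()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    best_eval = np.inf
    best_path = None

    for epoch in range(tcfg.epochs):
        lr = lr_at_epoch(tcfg, epoch)
        order = rng.permutation(len(dataset))
        epoch_losses: list[float] = []
        for start in range(0, len(order), tcfg.batch):
            idx = order[start : start + tcfg.batch]
            optimizer.zero_grad()
            batch_losses = [
                _pair_loss(model, dataset[i], partition, with_grad=True)
                for i in idx
            ]
            loss = float(np.mean(batch_losses))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch}, "
                    f"step {start // tcfg.batch}; aborting"
                )
            for p in model.parameters():
                p.grad /= len(idx)
            optimizer.step(lr)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        if eval_dataset:
            eval_loss = float(
                np.mean(
                    [
                        _pair_loss(model, pair, partition, with_grad=False)
                        for pair in eval_dataset
                    ]
                )
            )
        else:
            eval_loss = float("nan")
        history.train_loss.append(train_loss)
        history.eval_loss.append(eval_loss)
        history.lr.append(lr)
        logger.info(
            "epoch %d: train loss %.5f, eval loss %.5f, lr %.2e",
            epoch,
            train_loss,
            eval_loss,
            lr,
        )
        if out_path is not None and (epoch + 1) % tcfg.checkpoint_every == 0:
            ckpt = out_path / f"epoch_{epoch:04d}.npz"
            save_checkpoint(model, ckpt)
            history.checkpoint_paths.append(str(ckpt))
            if eval_dataset and eval_loss < best_eval:
                best_eval = eval_loss
                best_path = ckpt

    if tcfg.select_best and best_path is not None:
        from .unet_model import load_checkpoint

        model = load_checkpoint(best_path)
    return model, history
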