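"""Optimization loop: warmup schedule, window re-sampling, checkpointing.

Each time a document is viewed a *fresh* training window is sampled from it
(uniformly over sentence starts), so repeated passes see different slices
of every abstract.  The learning rate ramps linearly over the warmup steps
and stays flat afterwards.  "Epoch" here means one pass over a configurable
fraction of the corpus (default 5%), which is also the checkpoint cadence.

Two optimizers are provided: plain Adam (the desk-scale default) and LAMB,
the layerwise-adaptive variant designed for very large effective batches,
which rescales each parameter's Adam update by the ratio of the parameter
norm to the update norm.  Gradient accumulation supplies large effective
batch sizes on small machines.

Checkpoints carry the full training state — parameters, optimizer moments,
generator state and corpus cursor — so :func:`resume_training` continues a
run with a loss trajectory identical to the uninterrupted one.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import model as M
from .corpus import DocumentTrack, sample_window


@dataclass
class TrainConfig:
    """Optimization settings.

    ``batch_size`` is the *effective* batch (480 at full scale; 16 is a
    sensible desk default); when it exceeds ``micro_batch_size`` the
    difference is made up by gradient accumulation.
    """

    batch_size: int = 16
    micro_batch_size: int | None = None
    learning_rate: float = 0.001
    warmup_steps: int = 500
    checkpoint_fraction: float = 0.05
    max_steps: int = 1000
    window: int = 128
    seed: int = 13
    optimizer: str = "adam"        # "adam" or "lamb"
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")
        if not 0.0 < self.checkpoint_fraction <= 1.0:
            raise ValueError("checkpoint_fraction must lie in (0, 1]")
        if self.optimizer not in ("adam", "lamb"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.micro_batch_size is None:
            self.micro_batch_size = self.batch_size


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Linear warmup to the base rate, flat afterwards (no decay)."""
    if step < 1:
        raise ValueError("step counts from 1")
    if step <= config.warmup_steps:
        return config.learning_rate * step / config.warmup_steps
    return config.learning_rate


class AdaptiveMomentOptimizer:
    """Adam, optionally with the LAMB per-parameter trust ratio."""

    def __init__(self, params: M.ModelParams, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 lamb: bool = False) -> None:
        self.named = list(params.named_tensors())
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lamb = lamb
        self.t = 0
        self.m = {name: np.zeros_like(t.data) for name, t in self.named}
        self.v = {name: np.zeros_like(t.data) for name, t in self.named}

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, p in self.named:
            g = p.grad
            if g is None:
                continue
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            if self.lamb:
                pn = np.linalg.norm(p.data)
                un = np.linalg.norm(update)
                trust = pn / un if pn > 0 and un > 0 else 1.0
                update = trust * update
            p.data -= lr * update

    def zero_grad(self) -> None:
        for _, p in self.named:
            p.grad = None

    def state(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for name in self.m:
            out[f"m:{name}"] = self.m[name]
            out[f"v:{name}"] = self.v[name]
        return out

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for name in self.m:
            self.m[name] = np.array(state[f"m:{name}"])
            self.v[name] = np.array(state[f"v:{name}"])


def make_optimizer(params: M.ModelParams, config: TrainConfig,
                   ) -> AdaptiveMomentOptimizer:
    return AdaptiveMomentOptimizer(params, weight_decay=config.weight_decay,
                                   lamb=(config.optimizer == "lamb"))


@dataclass
class TrainResult:
    loss_log: list[dict] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)


@dataclass
class _LoopState:
    """Everything beyond the parameters needed to resume a run exactly."""

    rng: np.random.Generator
    order: np.ndarray
    cursor: int
    docs_viewed: int
    step: int

    def to_arrays(self) -> dict:
        rng_json = json.dumps(self.rng.bit_generator.state).encode()
        return {
            "loop_rng": np.frombuffer(rng_json, dtype=np.uint8),
            "loop_order": self.order,
            "loop_cursor": np.asarray(self.cursor),
            "loop_docs_viewed": np.asarray(self.docs_viewed),
        }

    @classmethod
    def from_arrays(cls, arrays: dict, step: int) -> "_LoopState":
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(bytes(arrays["loop_rng"]).decode())
        return cls(rng=rng, order=np.array(arrays["loop_order"]),
                   cursor=int(arrays["loop_cursor"]),
                   docs_viewed=int(arrays["loop_docs_viewed"]), step=step)


def _run(tracks: list[DocumentTrack], params: M.ModelParams,
         config: TrainConfig, opt: AdaptiveMomentOptimizer,
         state: _LoopState, n_steps: int,
         out_dir: str | None) -> TrainResult:
    result = TrainResult()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    docs_per_epoch = max(1, math.ceil(config.checkpoint_fraction * len(tracks)))
    next_ckpt = (state.docs_viewed // docs_per_epoch + 1) * docs_per_epoch
    micro = config.micro_batch_size
    assert micro is not None

    def checkpoint(tag: str) -> None:
        path = os.path.join(out_dir, f"ckpt_{tag}.npz")
        opt_state = opt.state()
        opt_state.update(state.to_arrays())
        M.save_checkpoint(path, params, step=state.step,
                          optimizer_state=opt_state)
        result.checkpoints.append(path)

    for _ in range(n_steps):
        state.step += 1
        batch_tracks: list[DocumentTrack] = []
        for _ in range(config.batch_size):
            if state.cursor >= len(state.order):
                state.order = state.rng.permutation(len(tracks))
                state.cursor = 0
            batch_tracks.append(tracks[state.order[state.cursor]])
            state.cursor += 1
        state.docs_viewed += len(batch_tracks)
        windows = [sample_window(t, window=config.window, rng=state.rng)
                   for t in batch_tracks]

        opt.zero_grad()
        n_micro = math.ceil(len(windows) / micro)
        tot = 0.0
        comp_sums = {k: 0.0 for k in ("token", "pos", "dep", "ent")}
        for i in range(n_micro):
            part = windows[i * micro:(i + 1) * micro]
            batch = M.collate(part)
            out = M.forward(batch, params, mode="train", rng=state.rng)
            total, comp = M.multitask_loss(out, batch)
            weight = len(part) / len(windows)
            (total * weight).backward()
            tot += float(total.data) * weight
            for k, v in comp.items():
                comp_sums[k] += float(v.data) * weight
        if not np.isfinite(tot):
            raise RuntimeError(f"non-finite loss {tot!r} at step {state.step}; "
                               "aborting training")
        lr = lr_schedule(state.step, config)
        opt.step(lr)
        row = {"step": state.step, "lr": lr, "total": tot}
        row.update(comp_sums)
        result.loss_log.append(row)

        if out_dir and state.docs_viewed >= next_ckpt:
            checkpoint(f"{state.step:07d}")
            next_ckpt += docs_per_epoch

    if out_dir:
        checkpoint("final")
    return result


def train(tracks: list[DocumentTrack], params: M.ModelParams,
          config: TrainConfig, out_dir: str | None = None) -> TrainResult:
    """Run the optimization loop over pre-tokenized document tracks.

    Every step draws ``batch_size`` documents (cycling a seeded shuffled
    order) and samples a fresh window from each.  The per-step log records
    the learning rate, the four loss components and their sum; a non-finite
    loss aborts with a diagnostic naming the step.  Checkpoints (if
    ``out_dir`` is given) are written each time another
    ``checkpoint_fraction`` of the corpus has been viewed, plus a final
    one; runs are deterministic given the config seed.
    """
    if not tracks:
        raise ValueError("cannot train on an empty corpus")
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(params, config)
    state = _LoopState(rng=rng, order=rng.permutation(len(tracks)), cursor=0,
                       docs_viewed=0, step=0)
    return _run(tracks, params, config, opt, state, config.max_steps, out_dir)


def resume_training(checkpoint_path: str, tracks: list[DocumentTrack],
                    config: TrainConfig, n_steps: int,
                    out_dir: str | None = None,
                    ) -> tuple[M.ModelParams, TrainResult]:
    """Continue a checkpointed run for ``n_steps`` more steps.

    Restores parameters, optimizer moments, the window-sampling generator
    and the corpus cursor, so the continued loss trajectory matches the
    uninterrupted run exactly (same machine, same config).
    """
    params, step, opt_state = M.load_checkpoint(checkpoint_path)
    opt = make_optimizer(params, config)
    opt.load_state(opt_state)
    state = _LoopState.from_arrays(opt_state, step)
    return params, _run(tracks, params, config, opt, state, n_steps, out_dir)


def write_loss_log(loss_log: list[dict], path: str) -> None:
    """TSV loss log: step, lr, total and the four components."""
    cols = ["step", "lr", "total", "token", "pos", "dep", "ent"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in loss_log:
            fh.write("\t".join(repr(row[c]) for c in cols) + "\n")
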