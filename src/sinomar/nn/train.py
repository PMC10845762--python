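"""Patch extraction and RMSE/Adam training for the patch-to-patch networks.

Training pairs are (corrupted, ground-truth) 2-D arrays; patches are sampled
at aligned positions from both.  By default the sampling probability of a
position is proportional to the local |input - target| energy, which
concentrates patches on artifact-corrupted regions — uniform sampling is
available as ``sampling_weights="uniform"``.

The loss is the root-mean-square error per batch, sqrt(mean((pred - target)^2)),
optimized with Adam.  Intensities are linearly mapped to [0, 1] using the
min/max of the whole patch set; the map is stored on the model so inference
applies the same scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


from .layers import Param
from .models import _Model

__all__ = [
    "PatchSet",
    "TrainConfig",
    "TrainState",
    "extract_patches",
    "train_model",
    "Adam",
    "paper_preset",
    "desk_preset",
]


@dataclass
class PatchSet:
    """Aligned (input, target) patch pairs.

    ``inputs`` has shape ``(n, c, p, p)`` — channel 0 is the value channel,
    any further channels are auxiliary (e.g. a binary missing-data mask).
    ``targets`` has shape ``(n, 1, p, p)``.
    """

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if (
            self.inputs.ndim != 4
            or self.targets.ndim != 4
            or self.targets.shape[1] != 1
            or self.inputs.shape[0] != self.targets.shape[0]
            or self.inputs.shape[2:] != self.targets.shape[2:]
        ):
            raise ValueError("need (n, c, p, p) inputs aligned with (n, 1, p, p) targets")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[1]

    @property
    def intensity_range(self) -> tuple[float, float]:
        """Min/max over the value channel and the targets."""
        lo = float(min(self.inputs[:, :1].min(), self.targets.min()))
        hi = float(max(self.inputs[:, :1].max(), self.targets.max()))
        if hi <= lo:
            hi = lo + 1.0  # constant data: degenerate but well-defined scaling
        return lo, hi


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The reference-scale presets (see :func:`paper_preset`) are 180,000/18,000
    patches, 100 epochs, learning rate 1e-5 for the sinogram U-Net and
    458,640/80,000 patches, 1300 epochs, learning rate 1e-3 for the image
    ResU-Net — both Adam with RMSE loss.  Desk-scale presets are much smaller.
    """

    n_train_patches: int = 600
    n_val_patches: int = 80
    epochs: int = 24
    learning_rate: float = 1e-3
    batch_size: int = 16
    optimizer: str = "adam"
    loss: str = "rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_val_patches >= self.n_train_patches:
            raise ValueError("n_val_patches must be smaller than n_train_patches")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam" or self.loss != "rmse":
            raise ValueError("only Adam optimization of the RMSE loss is supported")


def paper_preset(kind: str) -> TrainConfig:
    """Reference-scale training settings (cluster-scale; not test defaults)."""
    if kind == "modified_unet":
        return TrainConfig(180_000, 18_000, epochs=100, learning_rate=1e-5)
    if kind == "modified_resunet":
        return TrainConfig(458_640, 80_000, epochs=1300, learning_rate=1e-3)
    raise ValueError(f"unknown network kind {kind!r}")


def desk_preset(kind: str, seed: int = 0) -> TrainConfig:
    """Desk-scale settings that train in a few minutes on one CPU."""
    if kind == "modified_unet":
        return TrainConfig(600, 80, epochs=24, learning_rate=1e-3, seed=seed)
    if kind == "modified_resunet":
        return TrainConfig(500, 80, epochs=20, learning_rate=1e-3, seed=seed)
    raise ValueError(f"unknown network kind {kind!r}")


@dataclass
class TrainState:
    """Per-epoch loss histories and the best-validation weights."""

    epoch: int = 0
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    initial_val_loss: float = np.nan
    best_val_loss: float = np.inf
    best_weights: list[np.ndarray] | None = None


def extract_patches(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    patch_size: int,
    n_patches: int,
    sampling_weights: str | None = "artifact",
    seed: int = 0,
) -> PatchSet:
    """Draw aligned patch pairs from a list of (input, target) 2-D arrays.

    ``sampling_weights='artifact'`` weights each candidate position by the
    total |input - target| inside the patch (artifact-energy emphasis);
    ``'uniform'`` or ``None`` samples positions uniformly; ``'mixed'`` is an
    equal mixture of the two, emphasizing corrupted regions while still
    covering easy ones.  Reproducible for a fixed seed.
    """
    if n_patches <= 0:
        raise ValueError("n_patches must be positive")
    rng = np.random.default_rng(seed)
    norm_pairs = []
    for inp, tgt in pairs:
        inp = np.asarray(inp, float)
        tgt = np.asarray(tgt, float)
        if inp.ndim == 2:
            inp = inp[None]
        if inp.shape[1:] != tgt.shape:
            raise ValueError("input/target shapes differ")
        norm_pairs.append((inp, tgt))
    n_channels = norm_pairs[0][0].shape[0]
    positions = []  # (pair index, row, col)
    weights = []
    p = patch_size
    for idx, (inp, tgt) in enumerate(norm_pairs):
        if inp.shape[0] != n_channels:
            raise ValueError("inconsistent channel counts across pairs")
        h, w = tgt.shape
        if h < p or w < p:
            raise ValueError(f"array {tgt.shape} smaller than patch size {p}")
        rows = np.arange(h - p + 1)
        cols = np.arange(w - p + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        positions.append(
            np.column_stack([np.full(rr.size, idx), rr.ravel(), cc.ravel()])
        )
        if sampling_weights in ("artifact", "mixed"):
            # exact per-position patch energy sum(|diff|) via an integral
            # image over the value channel
            s = np.zeros((h + 1, w + 1))
            s[1:, 1:] = np.cumsum(np.cumsum(np.abs(inp[0] - tgt), axis=0), axis=1)
            energy = s[p:, p:] - s[:-p, p:] - s[p:, :-p] + s[:-p, :-p]
            # cancellation in the cumsums can leave tiny negatives
            weights.append(np.clip(energy.ravel(), 0.0, None) + 1e-12)
        else:
            weights.append(np.ones(rr.size))
    positions = np.concatenate(positions)
    weights = np.concatenate(weights)
    prob = weights / weights.sum()
    if sampling_weights == "mixed":
        prob = 0.5 * prob + 0.5 / len(prob)
    chosen = rng.choice(len(positions), size=n_patches, replace=True, p=prob)
    ins = np.empty((n_patches, n_channels, p, p))
    tgts = np.empty((n_patches, 1, p, p))
    for k, (idx, r, c) in enumerate(positions[chosen]):
        inp, tgt = norm_pairs[idx]
        ins[k] = inp[:, r : r + p, c : c + p]
        tgts[k, 0] = tgt[r : r + p, c : c + p]
    return PatchSet(ins, tgts)


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _rmse_loss_and_grad(pred: np.ndarray, target: np.ndarray):
    err = pred - target
    loss = float(np.sqrt(np.mean(err**2)))
    if loss < 1e-15:
        return loss, np.zeros_like(err)
    return loss, err / (err.size * loss)


class TrainingFailure(RuntimeError):
    pass


def train_model(
    model: _Model,
    patchset: PatchSet,
    config: TrainConfig,
    val_patchset: PatchSet | None = None,
    val_fn=None,
    val_every: int = 1,
) -> TrainState:
    """Train ``model`` on ``patchset`` with Adam on the RMSE loss.

    If ``val_patchset`` is given it is used for validation as-is — the
    recommended setup is to draw it from *held-out phantoms* so that early
    stopping measures generalization to new objects rather than to new
    patches of the training objects.  Otherwise the patch set is shuffled
    once (seeded) and split into ``n_train_patches`` / ``n_val_patches``.

    ``val_fn`` (a zero-argument callable returning a scalar) overrides the
    patch-based validation loss for early stopping; it is evaluated before
    training and every ``val_every`` epochs.  Use it to stop on the actual
    task error (e.g. full-sinogram completion RMSE on held-out phantoms),
    which is what matters when patch losses and task errors weight regions
    differently.

    Per-epoch mean training loss and validation loss are recorded; the
    returned state carries the weights with the best validation loss, which
    are also installed on the model.  Fully deterministic for a fixed seed in
    single-threaded execution.
    """
    rng = np.random.default_rng(config.seed)
    if val_patchset is None:
        n_total = config.n_train_patches + config.n_val_patches
        if len(patchset) < n_total:
            raise ValueError(
                f"patch set has {len(patchset)} patches, need {n_total} for this split"
            )
        order = rng.permutation(len(patchset))[:n_total]
        tr, va = order[: config.n_train_patches], order[config.n_train_patches :]
        train_in, train_tgt = patchset.inputs[tr], patchset.targets[tr]
        val_in, val_tgt = patchset.inputs[va], patchset.targets[va]
        lo, hi = patchset.intensity_range
    else:
        if len(patchset) < config.n_train_patches:
            raise ValueError(
                f"patch set has {len(patchset)} patches, need {config.n_train_patches}"
            )
        tr = rng.permutation(len(patchset))[: config.n_train_patches]
        train_in, train_tgt = patchset.inputs[tr], patchset.targets[tr]
        val_in, val_tgt = val_patchset.inputs, val_patchset.targets
        lo = min(patchset.intensity_range[0], val_patchset.intensity_range[0])
        hi = max(patchset.intensity_range[1], val_patchset.intensity_range[1])
    model.set_normalization(lo, hi)

    vc = getattr(model, "value_channels", 1)

    def norm_inputs(x):
        z = x.astype(model.dtype).copy()
        z[:, :vc] = model.normalize(x[:, :vc]).astype(model.dtype)
        return z

    x_tr = norm_inputs(train_in)
    y_tr = model.normalize(train_tgt).astype(model.dtype)
    x_va = norm_inputs(val_in)
    y_va = model.normalize(val_tgt).astype(model.dtype)

    def patch_val_loss() -> float:
        err = []
        for i in range(0, x_va.shape[0], 64):
            pred = model.forward(x_va[i : i + 64])
            err.append((pred - y_va[i : i + 64]).ravel())
        e = np.concatenate(err)
        return float(np.sqrt(np.mean(e**2)))

    val_loss = val_fn if val_fn is not None else patch_val_loss

    state = TrainState()
    state.initial_val_loss = val_loss()
    state.best_val_loss = state.initial_val_loss
    state.best_weights = [p.value.copy() for p in model.params()]
    opt = Adam(model.params(), config.learning_rate)
    n_tr = x_tr.shape[0]
    for epoch in range(config.epochs):
        perm = rng.permutation(n_tr)
        losses = []
        for i in range(0, n_tr, config.batch_size):
            sel = perm[i : i + config.batch_size]
            model.zero_grad()
            pred = model.forward(x_tr[sel])
            loss, dpred = _rmse_loss_and_grad(pred, y_tr[sel])
            if not np.isfinite(loss):
                raise TrainingFailure(
                    f"non-finite training loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        state.epoch = epoch + 1
        state.train_loss.append(float(np.mean(losses)))
        if (epoch + 1) % val_every == 0 or epoch == config.epochs - 1:
            vl = val_loss()
            if vl < state.best_val_loss:
                state.best_val_loss = vl
                state.best_weights = [p.value.copy() for p in model.params()]
        else:
            vl = state.val_loss[-1] if state.val_loss else state.initial_val_loss
        state.val_loss.append(vl)
    # install best-validation weights
    for p, w in zip(model.params(), state.best_weights):
        p.value = w.copy()
    return state
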