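"""Loss functions and the adversarial training loop.

The generator is trained against a composite loss

    l_generator = L1{z, G(x, c)} + lambda * TV{G(x, c)}
                  + alpha * (1 - D(G(x, c), c))^2

and the discriminator against the squared-error adversarial loss

    l_discriminator = D(G(x, c), c)^2 + (1 - D(z, c))^2,

where z is the stained target, x the autofluorescence stack and c the
staining matrix.  Defaults follow the reference schedule: lambda = 0.02,
alpha = 2000, Adam with learning rates 1e-4 (generator) and 2e-6
(discriminator), ten generator updates per discriminator update, batch
size 8.

The public :func:`total_variation` and :func:`l1_distance` operators
implement the anisotropic TV sum and the per-pixel mean absolute error
exactly.  Inside the loop the TV term is placed on the same per-pixel scale
as the L1 term (divided by the pixel-and-channel count) so that the
lambda = 0.02 setting yields a TV contribution of a few percent of the L1
loss, the balance the schedule was designed around; see the methods note.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network import Discriminator, Generator
from .nn import Adam
from .preprocessing import PatchPair

__all__ = [
    "LossRecord",
    "TrainingConfig",
    "TrainingDivergedError",
    "discriminator_loss",
    "generator_loss",
    "l1_distance",
    "total_variation",
    "train",
]


class TrainingDivergedError(RuntimeError):
    """A loss became non-finite; carries the last good step index."""

    def __init__(self, step: int, message: str) -> None:
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass
class TrainingConfig:
    """Hyperparameters of the adversarial schedule (reference defaults)."""

    lam: float = 0.02
    alpha: float = 2000.0
    lr_generator: float = 1e-4
    lr_discriminator: float = 2e-6
    generator_steps_per_discriminator_step: int = 10
    batch_size: int = 8
    total_discriminator_steps: int = 100
    seed: int = 0
    checkpoint_every: int = 50  # discriminator steps between snapshots

    def __post_init__(self) -> None:
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if self.generator_steps_per_discriminator_step < 1:
            raise ValueError("step ratio must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class LossRecord:
    """Losses at one generator step (components sum to the total)."""

    step: int
    total: float
    l1: float
    tv: float  # the weighted lambda * TV/(P*Q*C) contribution
    adversarial: float  # the weighted alpha * (1 - D)^2 contribution
    discriminator: float | None = None  # filled on discriminator steps


def total_variation(z: np.ndarray) -> float:
    """Anisotropic total variation: sum of absolute neighbour differences.

    TV(z) = sum_p sum_q |z[p+1,q] - z[p,q]| + |z[p,q+1] - z[p,q]|, with
    out-of-range neighbour terms omitted at the last row/column; channels of
    multi-channel images are summed.
    """
    z = np.asarray(z, dtype=np.float64)
    return float(
        np.abs(np.diff(z, axis=0)).sum() + np.abs(np.diff(z, axis=1)).sum()
    )


def _tv_gradient(z: np.ndarray) -> np.ndarray:
    g = np.zeros_like(z)
    dv = np.sign(np.diff(z, axis=0))
    g[1:] += dv
    g[:-1] -= dv
    dh = np.sign(np.diff(z, axis=1))
    g[:, 1:] += dh
    g[:, :-1] -= dh
    return g


def l1_distance(z: np.ndarray, g: np.ndarray) -> float:
    """Mean absolute error over pixels (and channels): Eq. of the L1 norm."""
    z = np.asarray(z, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if z.shape != g.shape:
        raise ValueError(f"image shapes differ: {z.shape} vs {g.shape}")
    return float(np.abs(z - g).mean())


def generator_loss(
    z_label: np.ndarray,
    x_input: np.ndarray,
    condition: np.ndarray,
    G: Callable[[np.ndarray, np.ndarray], np.ndarray],
    D: Callable[[np.ndarray, np.ndarray], float],
    lam: float = 0.02,
    alpha: float = 2000.0,
) -> tuple[float, dict[str, float]]:
    """Composite generator loss, exactly as printed (TV unnormalized).

    ``G(x, c)`` maps the input and staining matrix to an image; ``D(img, c)``
    returns a score in (0, 1).  Returns (total, components).
    """
    g_out = np.asarray(G(x_input, condition), dtype=np.float64)
    d_out = float(np.asarray(D(g_out, condition)).mean())
    l1 = l1_distance(z_label, g_out)
    tv = lam * total_variation(g_out)
    adv = alpha * (1.0 - d_out) ** 2
    total = l1 + tv + adv
    if not np.isfinite(total):
        raise TrainingDivergedError(-1, f"generator loss non-finite: {l1}, {tv}, {adv}")
    return total, {"l1": l1, "tv": tv, "adversarial": adv}


def discriminator_loss(
    z_label: np.ndarray,
    x_input: np.ndarray,
    condition: np.ndarray,
    G: Callable[[np.ndarray, np.ndarray], np.ndarray],
    D: Callable[[np.ndarray, np.ndarray], float],
) -> float:
    """Squared-error adversarial loss: D(G(x,c),c)^2 + (1 - D(z,c))^2."""
    g_out = np.asarray(G(x_input, condition), dtype=np.float64)
    d_fake = float(np.asarray(D(g_out, condition)).mean())
    d_real = float(np.asarray(D(z_label, condition)).mean())
    loss = d_fake**2 + (1.0 - d_real) ** 2
    if not np.isfinite(loss):
        raise TrainingDivergedError(-1, f"discriminator loss non-finite: {loss}")
    return loss


# ---------------------------------------------------------------------------
# Batch assembly and the loop


def assemble_batch(
    patches: Sequence[PatchPair], n_stains: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack patches into (x, z, condition) arrays; x = [channels | c~]."""
    conds = []
    for p in patches:
        if p.weights.ndim == 1:
            h, w = p.channels.shape[:2]
            conds.append(np.broadcast_to(p.weights, (h, w, n_stains)))
        else:
            conds.append(p.weights)
    cond = np.stack(conds).astype(np.float32)
    chan = np.stack([p.channels for p in patches]).astype(np.float32)
    z = np.stack([p.target for p in patches]).astype(np.float32)
    x = np.concatenate([chan, cond], axis=3)
    return x, z, cond


class _BatchSampler:
    """Seeded shuffling sampler yielding index batches without replacement."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator) -> None:
        self.n = n
        self.batch_size = batch_size
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._pos >= self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        out = self._order[self._pos : self._pos + self.batch_size]
        self._pos += len(out)
        return out


def train(
    dataset: Sequence[PatchPair],
    generator: Generator,
    discriminator: Discriminator,
    config: TrainingConfig,
    callback: Callable[[LossRecord], None] | None = None,
) -> tuple[Generator, list[LossRecord]]:
    """Run the alternating adversarial loop.

    For each of ``config.total_discriminator_steps`` outer steps, the
    generator takes ``generator_steps_per_discriminator_step`` Adam updates
    on fresh batches, then the discriminator takes one update with fakes
    regenerated from the current generator.  All randomness (shuffling)
    derives from ``config.seed``.  Returns the trained generator and the
    loss history; on a non-finite loss the models are restored to the last
    snapshot and :class:`TrainingDivergedError` is raised.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    n_stains = generator.spec.n_stains
    rng = np.random.default_rng(config.seed)
    sampler = _BatchSampler(len(dataset), config.batch_size, rng)
    opt_g = Adam(generator.params(), lr=config.lr_generator)
    opt_d = Adam(discriminator.params(), lr=config.lr_discriminator)
    history: list[LossRecord] = []
    snapshot = _snapshot(generator, discriminator)
    snapshot_step = 0
    gstep = 0
    for dstep in range(config.total_discriminator_steps):
        for _ in range(config.generator_steps_per_discriminator_step):
            idx = sampler.next()
            x, z, cond = assemble_batch([dataset[i] for i in idx], n_stains)
            n, h, w, c = z.shape
            fake = generator.forward(x)
            d_fake = discriminator.forward(fake, cond)

            err = fake - z
            l1 = float(np.abs(err).mean())
            tv_sum = sum(total_variation(fake[i]) for i in range(n))
            tv_term = config.lam * tv_sum / (n * h * w * c)
            adv_vals = (1.0 - d_fake) ** 2
            adv_term = config.alpha * float(adv_vals.mean())
            total = l1 + tv_term + adv_term
            if not np.isfinite(total):
                _restore(generator, discriminator, snapshot)
                raise TrainingDivergedError(
                    gstep, f"generator loss non-finite (restored to step {snapshot_step})"
                )

            grad = np.sign(err) / err.size
            tv_grads = np.stack([_tv_gradient(fake[i]) for i in range(n)])
            grad = grad + config.lam / (n * h * w * c) * tv_grads
            # adversarial term: d/dG alpha*(1-D)^2 = -2 alpha (1-D) dD/dG
            opt_d.zero_grad()  # discard D param grads from this pass
            d_grad_score = -2.0 * config.alpha * (1.0 - d_fake) / n
            gi, _ = discriminator.backward(d_grad_score)
            grad = grad + gi
            opt_g.zero_grad()
            generator.backward(grad.astype(np.float32))
            opt_g.step()
            rec = LossRecord(
                step=gstep, total=total, l1=l1, tv=tv_term, adversarial=adv_term
            )
            history.append(rec)
            if callback:
                callback(rec)
            gstep += 1

        # discriminator update with fakes regenerated from the current G
        idx = sampler.next()
        x, z, cond = assemble_batch([dataset[i] for i in idx], n_stains)
        fake = generator.forward(x)
        n = len(idx)
        opt_d.zero_grad()
        d_fake = discriminator.forward(fake, cond)
        discriminator.backward(2.0 * d_fake / n)
        d_real = discriminator.forward(z, cond)
        discriminator.backward(-2.0 * (1.0 - d_real) / n)
        d_loss = float((d_fake**2).mean() + ((1.0 - d_real) ** 2).mean())
        if not np.isfinite(d_loss):
            _restore(generator, discriminator, snapshot)
            raise TrainingDivergedError(
                gstep, f"discriminator loss non-finite (restored to step {snapshot_step})"
            )
        opt_d.step()
        if history:
            history[-1].discriminator = d_loss
        if (dstep + 1) % config.checkpoint_every == 0:
            snapshot = _snapshot(generator, discriminator)
            snapshot_step = gstep
    return generator, history


def _snapshot(generator: Generator, discriminator: Discriminator) -> list[np.ndarray]:
    return [p.value.copy() for p in generator.params() + discriminator.params()]


def _restore(
    generator: Generator, discriminator: Discriminator, snapshot: list[np.ndarray]
) -> None:
    for p, v in zip(generator.params() + discriminator.params(), snapshot):
        p.value = v.copy()
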