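"""Free adversarial training on the input feature embeddings.

Each minibatch is replayed K consecutive times.  Every replay takes one
optimizer step on the combined clean + perturbed loss and reuses the input
gradient of that same backward pass to move the perturbation one
normalized step; the perturbation is projected back onto the L2 ball of
radius epsilon and reset between batches.  The outer epoch count is the
requested epoch budget divided by K (ceiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import Batch, JointEventModel, LossReport, make_batches
from .schema import AnnotatedSentence, SchemaError


@dataclass
class AdvConfig:
    alpha: float = 0.01  # perturbation factor
    free_k: int = 3  # inner replay count K
    literal_radius: bool = False  # radius alpha*D instead of alpha*sqrt(D)

    def __post_init__(self):
        if self.alpha <= 0:
            raise SchemaError("alpha must be positive")
        if self.free_k < 1:
            raise SchemaError("K must be at least 1")

    def epsilon(self, dim: int) -> float:
        # the customary radius scales with sqrt(D); the literal alpha*D
        # reading is kept available behind a switch
        return self.alpha * (dim if self.literal_radius else math.sqrt(dim))


def perturb_step(
    gradient: np.ndarray,
    r_prev: np.ndarray,
    epsilon: float,
    project: bool = True,
) -> np.ndarray:
    """One normalized ascent step of the perturbation, then projection.

    r <- r + epsilon * g / ||g|| (global L2); a zero gradient leaves r
    unchanged.  With ``project`` the result is clipped onto the epsilon
    ball.
    """
    if gradient.shape != r_prev.shape:
        raise SchemaError("gradient and perturbation shapes differ")
    norm = float(np.linalg.norm(gradient))
    r = r_prev if norm == 0.0 else r_prev + epsilon * gradient / norm
    if project:
        r_norm = float(np.linalg.norm(r))
        if r_norm > epsilon > 0:
            r = r * (epsilon / r_norm)
        elif epsilon == 0:
            r = np.zeros_like(r)
    return r


def adversarial_loss(
    model: JointEventModel,
    batch: Batch,
    r_adv: np.ndarray,
    dropout_masks: list[np.ndarray] | None = None,
):
    """Clean joint loss plus joint loss on the perturbed inputs.

    Returns (total Tensor, clean LossReport, perturbed LossReport, and the
    perturbed input Tensor whose gradient drives the next perturbation
    step).
    """
    clean_total, clean_report = model.loss(batch, dropout_masks=dropout_masks)
    x_pert = Tensor(batch.x + r_adv, requires_grad=True)
    pert_total, pert_report = model.loss(batch, x=x_pert, dropout_masks=dropout_masks)
    return clean_total + pert_total, clean_report, pert_report, x_pert


def train_freeat(
    model: JointEventModel,
    corpus: Sequence[AnnotatedSentence],
    epochs: int,
    adv: AdvConfig,
    rng: np.random.Generator | None = None,
    trace_r_norms: list[float] | None = None,
) -> list[LossReport]:
    """Adversarially train the joint model; returns per-step clean losses.

    ``epochs`` is the total iteration budget: the corpus is traversed
    ceil(epochs / K) times with K replays per batch, so the number of
    optimizer steps matches plain training on the same budget.
    """
    rng = rng or np.random.default_rng(model.config.seed)
    optimizer = ad.Adam(model.params(), lr=model.config.lr)
    trace: list[LossReport] = []
    corpus = list(corpus)
    epsilon = adv.epsilon(model.config.feature.total_dim)
    outer = math.ceil(epochs / adv.free_k)
    restart = model.config.restart_every
    for outer_i in range(outer):
        completed = outer_i * adv.free_k  # budget epochs consumed so far
        if restart > 0 and completed > 0 and completed % restart == 0:
            optimizer.reset_state()
        order = rng.permutation(len(corpus))
        batches = make_batches(
            model, [corpus[i] for i in order], model.config.batch_size
        )
        for batch in batches:
            r_adv = np.zeros_like(batch.x)
            if trace_r_norms is not None:
                trace_r_norms.append(float(np.linalg.norm(r_adv)))
            for _ in range(adv.free_k):
                dropout = model.dropout_masks(batch, rng)
                total, clean_report, _, x_pert = adversarial_loss(
                    model, batch, r_adv, dropout
                )
                optimizer.zero_grad()
                total.backward()
                # multiplex the same backward pass: parameters step on the
                # combined loss, r steps on the input gradient
                grad_x = x_pert.grad
                optimizer.step()
                r_adv = perturb_step(grad_x, r_adv, epsilon)
                trace.append(clean_report)
    return trace
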