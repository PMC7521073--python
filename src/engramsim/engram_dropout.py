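"""Dropout of engram nodes.

The package's central manipulation: randomly silencing units of the
100-neuron fully connected layer — the model's stand-in for engram
nodes (synapses recruited during memory encoding) — either while the
network learns (modelling stimulation around encoding) or only at
evaluation (modelling stimulation during recall).

Inverted dropout is used: kept units are rescaled by 1/(1 - rate) so the
expected activation is unchanged.  The rescaling at evaluation time can
be disabled for sensitivity analysis, but the default keeps a single
operator for both phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .nn_core import ConfigurationError, ForwardCache, NetworkParams, forward_pass

__all__ = ["DropoutPolicy", "DropoutMask", "sample_mask", "apply_dropout",
           "phased_forward"]

Phase = Literal["none", "train", "test"]


@dataclass(frozen=True)
class DropoutPolicy:
    """Where and how strongly engram dropout is applied.

    phase: "none" (identity), "train" (masks during learning only) or
    "test" (masks at evaluation only; training itself is dropout-free).
    rate: fraction of FC units dropped, in [0, 1).
    rescale: inverted-dropout rescaling of kept units by 1/(1 - rate).
    include_output: sensitivity option that additionally masks the
    class-score (output) units.  Off by default — the engram layer is
    the hidden FC layer — but masking the score layer at recall models a
    lesion that also silences readout nodes, which degrades recall far
    more sharply.
    per_sample: draw an independent mask per sample within a batch
    (standard dropout semantics, the default) rather than one mask
    shared by the whole batch.
    mask_seed: seed for standalone use of :func:`phased_forward`; the
    experiment harness supplies its own dropout RNG stream instead.
    """

    phase: Phase = "none"
    rate: float = 0.5
    rescale: bool = True
    include_output: bool = False
    per_sample: bool = True
    mask_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("none", "train", "test"):
            raise ConfigurationError(f"unknown dropout phase {self.phase!r}")
        if not 0.0 <= self.rate < 1.0:
            raise ConfigurationError(
                f"dropout rate must be in [0, 1), got {self.rate}"
            )

    def active_in(self, phase: Phase) -> bool:
        return self.phase == phase and self.phase != "none" and self.rate > 0.0


@dataclass
class DropoutMask:
    """Realized keep/drop pattern over the target layer's units.

    ``keep`` is (width,) for a batch-shared mask or (n, width) for
    per-sample masks; entries are exactly 0.0 or 1.0.
    """

    keep: np.ndarray

    @property
    def width(self) -> int:
        return self.keep.shape[-1]

    @property
    def realized_drop_fraction(self) -> float:
        return float(1.0 - self.keep.mean())


def sample_mask(width: int, rate: float, rng: np.random.Generator,
                n: int | None = None) -> DropoutMask:
    """Drop each unit independently with probability ``rate``.

    ``n`` requests a stack of per-sample masks of shape (n, width).
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError(f"dropout rate must be in [0, 1), got {rate}")
    shape = width if n is None else (n, width)
    keep = (rng.random(shape) >= rate).astype(float)
    return DropoutMask(keep=keep)


def apply_dropout(activations: np.ndarray, mask: DropoutMask, rate: float,
                  rescale: bool = True) -> np.ndarray:
    """Zero dropped units; rescale kept units by 1/(1 - rate) by default."""
    if activations.shape[-1] != mask.width:
        raise ConfigurationError(
            f"mask width {mask.width} != activation width "
            f"{activations.shape[-1]}"
        )
    scale = 1.0 / (1.0 - rate) if rescale else 1.0
    return activations * (mask.keep * scale)


def mask_multiplier(mask: DropoutMask, rate: float,
                    rescale: bool = True) -> np.ndarray:
    """Per-unit multiplier encoding the mask for the network engine."""
    scale = 1.0 / (1.0 - rate) if rescale else 1.0
    return mask.keep * scale


def phased_forward(params: NetworkParams, x: np.ndarray,
                   policy: DropoutPolicy, phase: Phase,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[ForwardCache, DropoutMask | None]:
    """Forward pass applying the policy's mask only when phases match.

    A fresh mask is sampled per call (one mask per batch); it is returned
    for the backward pass (train phase) or audit (test phase).  When the
    policy is inactive for ``phase`` the pass is bit-identical to the
    mask-free engine.
    """
    if not policy.active_in(phase):
        return forward_pass(params, x), None
    if rng is None:
        rng = np.random.default_rng(policy.mask_seed)
    n = x.shape[0] if policy.per_sample else None
    mask = sample_mask(params.shapes.fc_units, policy.rate, rng, n=n)
    mult = mask_multiplier(mask, policy.rate, policy.rescale)
    return forward_pass(params, x, mult), mask


def policy_multipliers(policy: DropoutPolicy, fc_units: int, n_classes: int,
                       rng: np.random.Generator, batch_size: int,
                       ) -> tuple[np.ndarray, np.ndarray | None]:
    """Sample the multipliers an active policy prescribes for one batch.

    Returns (fc_multiplier, output_multiplier); the latter is None
    unless ``policy.include_output`` is set.
    """
    n = batch_size if policy.per_sample else None
    fc_mult = mask_multiplier(sample_mask(fc_units, policy.rate, rng, n=n),
                              policy.rate, policy.rescale)
    out_mult = None
    if policy.include_output:
        out_mult = mask_multiplier(
            sample_mask(n_classes, policy.rate, rng, n=n),
            policy.rate, policy.rescale)
    return fc_mult, out_mult
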