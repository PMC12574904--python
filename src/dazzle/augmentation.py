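"""Dropout augmentation: synthetic dropout masks and their application.

Dropout augmentation regularizes network inference against the zero
inflation of single-cell data: at every training step a fresh Bernoulli(p)
mask M is drawn over all cells x genes positions and the masked entries of
the input are temporarily zeroed. Writing the noise term E = -X ⊙ M, the
augmented matrix is X' = X + E. Because the model only ever sees X', it
cannot overfit any particular realization of the (real or synthetic)
dropout pattern.

A one-time variant, :func:`inject_background_dropout`, permanently zeroes a
fraction of entries before training; it exists to emulate extra background
dropout noise in robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["DropoutMask", "sample_mask", "apply_mask", "inject_background_dropout"]


@dataclass
class DropoutMask:
    """Boolean cells x genes mask; True marks an entry zeroed by augmentation."""

    mask: np.ndarray
    p: float
    rng_state: dict | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def sample_mask(n: int, m: int, p: float, rng: np.random.Generator) -> DropoutMask:
    """Draw an n x m i.i.d. Bernoulli(p) dropout mask.

    Every position is eligible, including entries that are already zero
    (masking them is a no-op). Reusing a generator state reproduces the
    mask; advancing the generator yields independent masks.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"dropout probability must be in [0, 1], got {p}")
    state = rng.bit_generator.state
    mask = rng.random((n, m)) < p
    return DropoutMask(mask=mask, p=float(p), rng_state=state)


def apply_mask(x: ExpressionMatrix, mask: DropoutMask,
               ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Zero the masked entries: returns (X', E) with X' = X + E, E = -X ⊙ M.

    Unmasked entries are returned bit-identical.
    """
    if mask.shape != x.values.shape:
        raise ValueError(f"mask shape {mask.shape} != matrix shape {x.values.shape}")
    noise = -x.values * mask.mask
    x_aug = replace(x, values=x.values + noise)
    return x_aug, noise


def inject_background_dropout(x: ExpressionMatrix, q: float,
                              rng: np.random.Generator) -> ExpressionMatrix:
    """Permanently zero a random fraction q of entries (one-time, pre-training)."""
    if q == 0.0:
        return x
    mask = sample_mask(x.n_cells, x.n_genes, q, rng)
    x_bg, _ = apply_mask(x, mask)
    return x_bg
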