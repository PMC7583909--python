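"""Histogram fusion of per-phase feature vectors into fixed-size tensors.

Every RNA carries, for each feature category (k-mer, CTD, doc2vec, graph),
one vector per reading-frame phase. The fusion step turns each category
into one 20x20 histogram channel: the three phase vectors are min-max
normalized jointly to [0, 1], every feature dimension contributes one 2-D
point per phase pair ((0,1), (0,2), (1,2)) — coordinates are its values in
the two phases — and the channel is the 2-D histogram of those 3 x dims
points on a uniform 20x20 grid over [0, 1]^2. Stacking the four channels
gives the 20x20x4 tensor the convolutional classifier consumes.

This construction uses all three phases symmetrically, is deterministic,
conserves the point count per channel, and is invariant to permuting or
positively rescaling the dimensions within a category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureBundle

__all__ = ["FusedTensor", "fuse_histogram", "pair_tensor", "DEFAULT_BINS", "PHASE_PAIRS"]

DEFAULT_BINS = 20
PHASE_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass
class FusedTensor:
    """A bins x bins x n_categories histogram tensor for one RNA."""

    rna_id: str
    tensor: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be 3-D (bins, bins, channels)")
        if self.tensor.shape[2] != len(self.categories):
            raise ValueError("channel count must match categories")
        if np.any(self.tensor < 0):
            raise ValueError("histogram tensor must be non-negative")


def fuse_histogram(
    bundle: FeatureBundle,
    bins: int = DEFAULT_BINS,
    categories: tuple[str, ...] | None = None,
) -> FusedTensor:
    """Fuse a bundle's per-phase vectors into a bins x bins x n_cat tensor.

    Channel order follows ``categories`` (default: kmer, ctd, doc2vec, graph,
    restricted to what the bundle holds). Channel c sums to 3 x dims(c). A
    category whose values are all equal normalizes to 0, putting all mass in
    the corner cell.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if categories is None:
        categories = bundle.categories()
    if not categories:
        raise ValueError(f"bundle {bundle.rna_id!r} has no feature categories")
    edges = np.linspace(0.0, 1.0, bins + 1)
    channels = []
    for cat in categories:
        phases = np.stack([bundle.get(p, cat) for p in range(3)])  # (3, d)
        lo, hi = phases.min(), phases.max()
        norm = (phases - lo) / (hi - lo) if hi > lo else np.zeros_like(phases)
        xs = np.concatenate([norm[a] for a, _ in PHASE_PAIRS])
        ys = np.concatenate([norm[b] for _, b in PHASE_PAIRS])
        h, _, _ = np.histogram2d(xs, ys, bins=[edges, edges])
        channels.append(h)
    return FusedTensor(
        rna_id=bundle.rna_id,
        tensor=np.stack(channels, axis=-1),
        categories=tuple(categories),
    )


def pair_tensor(lnc: FusedTensor, mir: FusedTensor) -> tuple[np.ndarray, np.ndarray]:
    """Validate and return the (lncRNA tensor, miRNA tensor) classifier input."""
    if lnc.tensor.shape != mir.tensor.shape:
        raise ValueError(
            f"tensor shape mismatch: {lnc.tensor.shape} vs {mir.tensor.shape}"
        )
    return lnc.tensor, mir.tensor
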