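"""Feature fusion: ordered concatenation of named feature blocks.

The fused vector keeps the canonical block order — deep-learning (DL)
features first, then CKSNAP, then PCPseDNC, then DCC — and a registry of
(block, column range, feature names) so any slice of the fused matrix can
be traced back to its encoder.  Ablated subsets are allowed; the order of
the surviving blocks is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoders import FeatureBlock

CANONICAL_ORDER = ("DL", "CKSNAP", "PCPseDNC", "DCC")
# PseDNC may stand in for PCPseDNC in ablation studies
_ORDER_RANK = {**{n: i for i, n in enumerate(CANONICAL_ORDER)}, "PseDNC": 2}


@dataclass(frozen=True)
class RegistryEntry:
    block: str
    start: int
    stop: int
    feature_names: tuple


@dataclass
class FusedMatrix:
    """n x D fused feature matrix plus the block->column-range registry."""

    matrix: np.ndarray
    registry: list[RegistryEntry]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [n for e in self.registry for n in e.feature_names]

    @property
    def block_names(self) -> list[str]:
        return [e.block for e in self.registry]

    def block(self, name: str) -> np.ndarray:
        for e in self.registry:
            if e.block == name:
                return self.matrix[:, e.start : e.stop]
        raise KeyError(name)

    def block_of_column(self, col: int) -> str:
        for e in self.registry:
            if e.start <= col < e.stop:
                return e.block
        raise IndexError(col)

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.feature_names, index=index)


def fuse(blocks: list[FeatureBlock]) -> FusedMatrix:
    """Concatenate blocks column-wise in the canonical order.

    Blocks must have equal row counts and distinct, recognized names.
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate block names: {names}")
    unknown = [n for n in names if n not in _ORDER_RANK]
    if unknown:
        raise ValueError(f"unrecognized block names: {unknown} (expected {CANONICAL_ORDER})")
    rows = {b.matrix.shape[0] for b in blocks}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across blocks: {sorted(rows)}")
    ordered = sorted(blocks, key=lambda b: _ORDER_RANK[b.name])
    registry: list[RegistryEntry] = []
    start = 0
    for b in ordered:
        registry.append(RegistryEntry(b.name, start, start + b.n_features, tuple(b.feature_names)))
        start += b.n_features
    return FusedMatrix(np.hstack([b.matrix for b in ordered]), registry)
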