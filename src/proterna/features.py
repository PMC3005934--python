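"""Sliding-window feature encoding.

Residue *i* is represented by the profiles of itself and its 22 neighbours
(window size 23).  Each window position contributes 24 values: the 20
normalized PSSM scores, the three secondary-structure probabilities
(H, E, C), and a boundary flag that is 1 when the position falls outside
the sequence (its profile values are then zero).  The full vector is
23 × 24 = 552-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from proterna.profiles import ProfileSet


@dataclass(frozen=True)
class EncodingConfig:
    window: int = 23
    features_per_position: int = 24  # 20 PSSM + 3 SS + 1 boundary flag
    include_ss: bool = True
    include_boundary_flag: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        expected = 20 + 3 * self.include_ss + 1 * self.include_boundary_flag
        if self.features_per_position != expected:
            raise ValueError(
                f"features_per_position must be {expected} for these toggles"
            )

    @property
    def half_window(self) -> int:
        return self.window // 2

    @property
    def dimension(self) -> int:
        return self.window * self.features_per_position


@dataclass
class FeatureMatrix:
    """N×D window-feature rows; row i−1 encodes the residue at 1-based i."""

    rows: np.ndarray
    chain_id: str = ""

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))

    @property
    def n_residues(self) -> int:
        return self.rows.shape[0]


def _position_blocks(profiles: ProfileSet, config: EncodingConfig) -> np.ndarray:
    """Per-position 24-value blocks padded with half_window boundary blocks
    on each side (zero profiles, flag 1)."""
    n = profiles.n_residues
    f = config.features_per_position
    blocks = np.zeros((n + 2 * config.half_window, f))
    inside = slice(config.half_window, config.half_window + n)
    blocks[inside, :20] = profiles.pssm_normalized.T
    col = 20
    if config.include_ss:
        blocks[inside, 20:23] = profiles.ss.probs.T  # (H, E, C)
        col = 23
    if config.include_boundary_flag:
        blocks[:, col] = 1.0
        blocks[inside, col] = 0.0
    return blocks


def encode_residue(
    profiles: ProfileSet, index: int, config: EncodingConfig = EncodingConfig()
) -> np.ndarray:
    """Encode the residue at 1-based ``index`` as one window vector.

    Window offsets run −half..+half in order; out-of-sequence positions
    contribute zero profile values with the boundary flag set.
    """
    n = profiles.n_residues
    if not 1 <= index <= n:
        raise IndexError(f"residue index {index} outside 1..{n}")
    blocks = _position_blocks(profiles, config)
    start = index - 1  # padded array already offset by half_window
    return blocks[start : start + config.window].ravel()


def encode_chain(
    profiles: ProfileSet, config: EncodingConfig = EncodingConfig()
) -> FeatureMatrix:
    """Encode every residue of a chain; row i−1 equals
    ``encode_residue(profiles, i)``."""
    if profiles.n_residues == 0:
        raise ValueError("profiles must cover at least one residue")
    blocks = _position_blocks(profiles, config)
    windows = np.lib.stride_tricks.sliding_window_view(
        blocks, (config.window, config.features_per_position)
    )[:, 0]
    rows = windows.reshape(profiles.n_residues, config.dimension).copy()
    return FeatureMatrix(rows=rows, chain_id=profiles.chain_id)


def expected_boundary_flags(index: int, n: int, config: EncodingConfig = EncodingConfig()) -> int:
    """Closed-form count of boundary positions in the window at 1-based
    ``index`` on a chain of length ``n``."""
    h = config.half_window
    return max(0, h + 1 - index) + max(0, index - (n - h))


def write_features_tsv(features: FeatureMatrix) -> str:
    """Dense TSV with chain_id and 1-based residue index per row."""
    lines = ["chain_id\tresidue_index\t" + "\t".join(
        f"f{j}" for j in range(features.rows.shape[1])
    )]
    for i, row in enumerate(features.rows):
        vals = "\t".join(f"{v:.6f}" for v in row)
        lines.append(f"{features.chain_id}\t{i + 1}\t{vals}")
    return "\n".join(lines) + "\n"
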