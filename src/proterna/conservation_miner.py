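"""Conserved-residue pattern mining over homolog families.

A functional stand-in for discontinuous-pattern miners of the WildSpan
family: homolog sets are filtered to 30–90% identity to the query (at most
150 sequences), per-position conservation is measured by global alignment
to the query, and maximal conserved runs are chained through flexible gaps
into discontinuous patterns.  Conserved positions become predicted
RNA-binding residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align


class NoPatternError(RuntimeError):
    """Raised when the homolog set cannot support pattern mining (too few
    homologs after filtering, or all homologs too similar/dissimilar)."""


@dataclass
class HomologSet:
    """A query sequence with its filtered homologs.

    Each homolog is ``(id, sequence, identity-to-query)`` with identity as a
    fraction in (0, 1].
    """

    query: tuple[str, str]
    homologs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h[0] for h in self.homologs]
        if len(ids) != len(set(ids)):
            raise ValueError("homolog ids must be unique")
        for _, _, ident in self.homologs:
            if not 0 < ident <= 1:
                raise ValueError(f"identity {ident} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.homologs)


@dataclass(frozen=True)
class MinerConfig:
    min_identity: float = 0.30
    max_identity: float = 0.90
    max_homologs: int = 150
    min_homologs: int = 3  # below this, no pattern is possible
    min_block_len: int = 3
    min_support: float = 0.8
    max_gap: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.min_identity < self.max_identity <= 1:
            raise ValueError("need 0 < min_identity < max_identity <= 1")
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of conserved query positions (1-based, inclusive)."""

    query_start: int
    query_end: int
    support: float

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("block start after end")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class WPattern:
    """Ordered conserved blocks linked by flexible gaps."""

    blocks: list[ConservedBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("pattern needs at least one block")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.query_start <= prev.query_end:
                raise ValueError("pattern blocks must be sorted and disjoint")


def filter_homologs(
    hits: Sequence[tuple[str, str, float]],
    config: MinerConfig = MinerConfig(),
    query: tuple[str, str] = ("query", ""),
) -> HomologSet:
    """Apply the identity window, deduplicate by sequence, and cap the set.

    Hits outside [min_identity, max_identity] are discarded; if more than
    ``max_homologs`` survive, the highest-identity hits are kept (ties by
    id for determinism).
    """
    in_window = [
        h for h in hits if config.min_identity <= h[2] <= config.max_identity
    ]
    seen: set[str] = set()
    unique: list[tuple[str, str, float]] = []
    for h in in_window:
        if h[1] not in seen:
            seen.add(h[1])
            unique.append(h)
    if len(unique) > config.max_homologs:
        unique = sorted(unique, key=lambda h: (-h[2], h[0]))[: config.max_homologs]
    return HomologSet(query=query, homologs=unique)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def conservation_vector(homolog_set: HomologSet) -> np.ndarray:
    """Fraction of homologs matching the query residue at each position.

    Each homolog is globally aligned to the query (identity scoring, gap
    open −10 / extend −1); a homolog supports query position *i* when its
    aligned residue there is identical to the query's.  Gapped positions
    count as non-conserved.
    """
    query = homolog_set.query[1]
    if not homolog_set.homologs:
        raise NoPatternError(
            "no pattern possible: not enough homologous proteins"
        )
    aligner = _make_aligner()
    n = len(query)
    matches = np.zeros(n, dtype=float)
    for _, seq, _ in homolog_set.homologs:
        if seq == query:
            matches += 1.0
            continue
        aln = aligner.align(query, seq)[0]
        for (q_start, q_end), (t_start, t_end) in zip(*aln.aligned):
            block_q = np.arange(q_start, q_end)
            q_chars = np.frombuffer(query[q_start:q_end].encode(), dtype="S1")
            t_chars = np.frombuffer(seq[t_start:t_end].encode(), dtype="S1")
            matches[block_q] += q_chars == t_chars
    return matches / len(homolog_set.homologs)


def mine_patterns(
    homolog_set: HomologSet, config: MinerConfig = MinerConfig()
) -> list[WPattern]:
    """Mine discontinuous conservation patterns.

    Maximal runs with conservation ≥ ``min_support`` and length ≥
    ``min_block_len`` become blocks; consecutive blocks within ``max_gap``
    residues are chained into one pattern; larger gaps start a new pattern.
    Output is ordered by query start.
    """
    if len(homolog_set) < config.min_homologs:
        raise NoPatternError(
            f"no pattern possible: {len(homolog_set)} homologs after filtering "
            f"(need >= {config.min_homologs}); the set may contain too few or "
            "too similar homologous proteins"
        )
    cons = conservation_vector(homolog_set)
    blocks: list[ConservedBlock] = []
    i = 0
    n = len(cons)
    while i < n:
        if cons[i] >= config.min_support:
            j = i
            while j + 1 < n and cons[j + 1] >= config.min_support:
                j += 1
            if j - i + 1 >= config.min_block_len:
                blocks.append(
                    ConservedBlock(
                        query_start=i + 1,
                        query_end=j + 1,
                        support=float(np.mean(cons[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1

    patterns: list[WPattern] = []
    current: list[ConservedBlock] = []
    for block in blocks:
        if current and block.query_start - current[-1].query_end - 1 > config.max_gap:
            patterns.append(WPattern(blocks=current))
            current = []
        current.append(block)
    if current:
        patterns.append(WPattern(blocks=current))
    return patterns


def pattern_calls(patterns: Sequence[WPattern], query_length: int) -> np.ndarray:
    """Binary per-residue calls: 1 where any pattern block covers the
    position."""
    calls = np.zeros(query_length, dtype=int)
    for pattern in patterns:
        for block in pattern.blocks:
            if block.query_end > query_length or block.query_start < 1:
                raise ValueError(
                    f"block {block.query_start}-{block.query_end} outside "
                    f"query of length {query_length}"
                )
            calls[block.query_start - 1 : block.query_end] = 1
    return calls


def write_patterns_tsv(patterns: Sequence[WPattern]) -> str:
    lines = ["pattern_id\tblock_id\tstart\tend\tsupport"]
    for p, pattern in enumerate(patterns, start=1):
        for b, block in enumerate(pattern.blocks, start=1):
            lines.append(
                f"{p}\t{b}\t{block.query_start}\t{block.query_end}\t{block.support:.4f}"
            )
    return "\n".join(lines) + "\n"
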