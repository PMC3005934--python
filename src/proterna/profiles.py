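"""Readers for PSI-BLAST ASCII PSSMs and PSIPRED ``.ss2`` files, and the
logistic normalization that squashes log-odds scores into [0, 1].

The evolutionary profile of a residue is its column of the 20×N
position-specific scoring matrix; predicted secondary structure contributes
three per-residue probabilities (helix, strand, coil).  Together they form
the 23 per-residue evidence values consumed by the window encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: amino-acid column order of the blastpgp ASCII PSSM
PSSM_ALPHABET = list("ARNDCQEGHILKMFPSTWYV")


@dataclass
class PSSM:
    """Raw 20×N position-specific scoring matrix with its query sequence."""

    sequence: str
    raw: np.ndarray  # 20×N log-odds scores
    column_order: list[str] = field(default_factory=lambda: list(PSSM_ALPHABET))

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[0] != 20:
            raise ValueError("raw PSSM must be a 20×N matrix")
        if self.raw.shape[1] != len(self.sequence):
            raise ValueError("PSSM column count must match sequence length")

    @property
    def n_residues(self) -> int:
        return self.raw.shape[1]


@dataclass
class SecondaryStructureProfile:
    """3×N secondary-structure probabilities, rows ordered (H, E, C).

    PSIPRED emits (coil, helix, strand) columns; they are reordered here but
    never renormalized — the three values need not sum to 1.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float).reshape(3, -1)
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("secondary-structure probabilities outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.probs.shape[1]


@dataclass
class ProfileSet:
    """Per-chain evidence: normalized PSSM plus secondary structure."""

    pssm_normalized: np.ndarray  # 20×N in [0, 1]
    ss: SecondaryStructureProfile
    chain_id: str = ""

    def __post_init__(self) -> None:
        self.pssm_normalized = np.asarray(self.pssm_normalized, dtype=float)
        if self.pssm_normalized.shape != (20, self.ss.n_residues):
            raise ValueError("PSSM and secondary structure lengths differ")

    @property
    def n_residues(self) -> int:
        return self.pssm_normalized.shape[1]


class PSSMParseError(ValueError):
    """Malformed PSSM text; carries the 1-based offending line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"PSSM parse error at line {line_number}: {message}")


def read_pssm(text: str) -> PSSM:
    """Parse the blastpgp ``-Q`` ASCII PSSM dialect.

    Residue lines look like ``  1 M  -2 -1 ... (20 log-odds) (20 freqs) ...``;
    only the first 20 numeric columns (log-odds) are captured.
    """
    sequence: list[str] = []
    columns: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        # residue lines start with the 1-based index followed by the residue
        if not fields[0].isdigit():
            continue  # header / footer (lambda, K statistics)
        if len(fields) < 2 or len(fields[1]) != 1 or not fields[1].isalpha():
            continue
        values = fields[2:22]
        if len(values) < 20:
            raise PSSMParseError(lineno, f"expected 20 score columns, found {len(values)}")
        try:
            columns.append([float(v) for v in values])
        except ValueError as exc:
            raise PSSMParseError(lineno, str(exc)) from exc
        sequence.append(fields[1].upper())
    if not columns:
        raise PSSMParseError(0, "no residue lines found")
    raw = np.array(columns, dtype=float).T  # residues were rows in the file
    return PSSM(sequence="".join(sequence), raw=raw)


def write_pssm(pssm: PSSM) -> str:
    """Write a PSSM back to the blastpgp ASCII dialect (log-odds half only)."""

    def fmt(x: float) -> str:
        return f"{int(round(x)):>3d}" if float(x).is_integer() else f"{x:>7.3f}"

    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
        "            " + "   ".join(pssm.column_order)
    )
    lines = [header]
    for i in range(pssm.n_residues):
        scores = " ".join(fmt(v) for v in pssm.raw[:, i])
        lines.append(f"{i + 1:>5d} {pssm.sequence[i]}  {scores}")
    return "\n".join(lines) + "\n"


def normalize_pssm(pssm: PSSM | np.ndarray, squash=None) -> np.ndarray:
    """Map raw log-odds scores elementwise into (0, 1).

    The default squashing function is the logistic sigmoid
    ``f(x) = 1 / (1 + e^(-x))`` — the standard choice for PSSM features in
    this predictor family; it is strictly increasing with ``f(0) = 0.5``.
    An alternative callable can be supplied through ``squash``.
    """
    raw = pssm.raw if isinstance(pssm, PSSM) else np.asarray(pssm, dtype=float)
    if squash is not None:
        return np.asarray(squash(raw), dtype=float)
    # expit, written out to keep the formula visible
    return 1.0 / (1.0 + np.exp(-raw))


def read_ss2(text: str, expected_length: int | None = None) -> SecondaryStructureProfile:
    """Parse a PSIPRED ``.ss2`` file into (H, E, C)-ordered probabilities.

    ``.ss2`` body lines are ``idx aa state pC pH pE``; the three columns are
    reordered to the internal (helix, strand, coil) convention.
    """
    rows: list[tuple[float, float, float]] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 6 or not fields[0].isdigit():
            continue
        p_coil, p_helix, p_strand = (float(v) for v in fields[3:6])
        rows.append((p_helix, p_strand, p_coil))
    if expected_length is not None and len(rows) != expected_length:
        raise ValueError(
            f"ss2 has {len(rows)} residues, expected {expected_length}"
        )
    probs = np.array(rows, dtype=float).reshape(-1, 3).T
    return SecondaryStructureProfile(probs=probs)


def build_profile_set(
    pssm: PSSM, ss: SecondaryStructureProfile, chain_id: str = ""
) -> ProfileSet:
    """Normalize a raw PSSM and bundle it with secondary structure."""
    if ss.n_residues != pssm.n_residues:
        raise ValueError("PSSM and ss2 describe different lengths")
    return ProfileSet(
        pssm_normalized=normalize_pssm(pssm), ss=ss, chain_id=chain_id
    )


def write_profile_tsv(profiles: ProfileSet) -> str:
    """Cache a profile bundle as one TSV row per residue: 20 normalized PSSM
    columns followed by the (H, E, C) probabilities."""
    header = ["residue_index"] + [f"pssm_{a}" for a in PSSM_ALPHABET] + ["H", "E", "C"]
    lines = ["\t".join(header)]
    for i in range(profiles.n_residues):
        vals = list(profiles.pssm_normalized[:, i]) + list(profiles.ss.probs[:, i])
        lines.append("\t".join([str(i + 1)] + [f"{v:.6f}" for v in vals]))
    return "\n".join(lines) + "\n"


def read_profile_tsv(text: str, chain_id: str = "") -> ProfileSet:
    """Read a profile bundle written by :func:`write_profile_tsv`."""
    rows = []
    for line in text.splitlines():
        fields = line.strip().split("\t")
        if not fields or not fields[0].isdigit():
            continue
        rows.append([float(v) for v in fields[1:24]])
    arr = np.array(rows, dtype=float).reshape(-1, 23).T
    return ProfileSet(
        pssm_normalized=arr[:20],
        ss=SecondaryStructureProfile(probs=arr[20:23]),
        chain_id=chain_id,
    )
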