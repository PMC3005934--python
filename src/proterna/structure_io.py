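"""Structure parsing, interface labeling and dataset-construction filters.

A residue is called RNA-binding when at least one of its heavy atoms lies
within a distance cutoff (default 5.0 Å, inclusive) of any heavy atom of an
RNA chain in the same co-crystallized complex.  Dataset construction keeps
chains longer than 40 residues solved at 3.5 Å resolution or better, and
reduces sequence redundancy to at most 30% pairwise identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: names of ribonucleotide residues used for chain classification
_RNA_RESIDUES = {"A", "C", "G", "U"}

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, name, position and disorder bookkeeping."""

    element: str
    name: str
    coords: np.ndarray  # (3,) in Å
    residue_key: ResidueKey
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ProteinChain:
    """A protein chain as observed in the structure (ATOM records only).

    ``sequence`` uses the 20 standard one-letter codes plus ``X`` for
    residues without a standard parent; unresolved residues are absent.
    """

    chain_id: str
    sequence: str
    residue_keys: list[ResidueKey]
    atoms_by_residue: list[list[AtomRecord]]
    resolution: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residue_keys):
            raise ValueError("sequence and residue_keys lengths differ")
        if len(self.atoms_by_residue) != len(self.sequence):
            raise ValueError("atoms_by_residue misaligned with sequence")
        if any(len(atoms) == 0 for atoms in self.atoms_by_residue):
            raise ValueError("every residue must carry at least one atom")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RNAComponent:
    """An RNA chain reduced to its heavy-atom cloud."""

    chain_id: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("RNA component must contain atoms")


@dataclass
class LabeledChain:
    """A protein chain with its per-residue binding labels."""

    chain: ProteinChain
    labels: np.ndarray  # binary, aligned with chain.sequence
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.chain),):
            raise ValueError("labels must align with the chain sequence")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.labels = labels


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Collapse altloc duplicates: keep the highest occupancy, ties to the
    record that appears first in the file."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in atoms:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # dict preserves first-seen order, matching file order
    return list(chosen.values())


def parse_complex(
    structure_text: str, format: str = "pdb"
) -> tuple[list[ProteinChain], list[RNAComponent]]:
    """Parse a protein–RNA complex from PDB or mmCIF text.

    Every polymer chain is classified as protein (majority standard
    amino-acid residues) or RNA (majority A/C/G/U); other chains (waters,
    ligands, DNA) are ignored.  Hydrogens are dropped and altloc duplicates
    collapsed to the highest-occupancy record.

    Returns ``(protein_chains, rna_components)``; a structure missing either
    side yields the corresponding empty list.
    """
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(structure_text)
        elif fmt in ("mmcif", "cif"):
            doc = gemmi.cif.read_string(structure_text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown structure format: {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        raise ValueError(f"could not parse {fmt} structure: {exc}") from exc

    resolution = float(st.resolution) if st.resolution > 0 else None
    proteins: list[ProteinChain] = []
    rnas: list[RNAComponent] = []
    if len(st) == 0:
        return proteins, rnas

    model = st[0]
    for chain in model:
        n_aa = sum(_is_amino_acid(res.name) for res in chain)
        n_rna = sum(res.name.strip() in _RNA_RESIDUES for res in chain)
        n_res = len(chain)
        if n_res == 0:
            continue
        if n_aa * 2 > n_res:
            prot = _extract_protein(chain, resolution)
            if prot is not None:
                proteins.append(prot)
        elif n_rna * 2 > n_res:
            rna = _extract_rna(chain)
            if rna is not None:
                rnas.append(rna)
    return proteins, rnas


def _heavy_atoms(residue: gemmi.Residue, key: ResidueKey) -> list[AtomRecord]:
    kept = [a for a in residue if not a.element.is_hydrogen]
    return [
        AtomRecord(
            element=a.element.name,
            name=a.name,
            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
            residue_key=key,
            occupancy=min(max(a.occ, 0.0), 1.0),
            altloc=a.altloc if a.altloc != "\0" else "",
        )
        for a in _select_altloc(kept)
    ]


def _extract_protein(chain: gemmi.Chain, resolution: float | None) -> ProteinChain | None:
    seq: list[str] = []
    keys: list[ResidueKey] = []
    atoms: list[list[AtomRecord]] = []
    for res in chain:
        if not _is_amino_acid(res.name):
            continue
        key = (chain.name, res.seqid.num, res.seqid.icode.strip())
        records = _heavy_atoms(res, key)
        if not records:
            continue
        seq.append(_one_letter(res.name))
        keys.append(key)
        atoms.append(records)
    if not seq:
        return None
    return ProteinChain(
        chain_id=chain.name,
        sequence="".join(seq),
        residue_keys=keys,
        atoms_by_residue=atoms,
        resolution=resolution,
    )


def _extract_rna(chain: gemmi.Chain) -> RNAComponent | None:
    records: list[AtomRecord] = []
    for res in chain:
        if res.name.strip() not in _RNA_RESIDUES:
            continue
        key = (chain.name, res.seqid.num, res.seqid.icode.strip())
        records.extend(_heavy_atoms(res, key))
    if not records:
        return None
    return RNAComponent(chain_id=chain.name, atoms=records)


def label_binding_residues(
    chain: ProteinChain,
    rna: Sequence[RNAComponent],
    cutoff: float = 5.0,
) -> LabeledChain:
    """Label residues whose minimum heavy-atom distance to any RNA atom is
    within ``cutoff`` Å (inclusive).

    An empty RNA list yields all-zero labels with a warning rather than an
    error, so apo chains pass through the pipeline unlabeled.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(chain)
    rna_coords = np.array(
        [atom.coords for comp in rna for atom in comp.atoms], dtype=float
    ).reshape(-1, 3)
    if rna_coords.shape[0] == 0:
        warnings.warn(
            f"chain {chain.chain_id}: no RNA atoms; all labels set to 0",
            stacklevel=2,
        )
        return LabeledChain(chain=chain, labels=np.zeros(n, dtype=int), cutoff=cutoff)

    tree = cKDTree(rna_coords)
    labels = np.zeros(n, dtype=int)
    for i, atoms in enumerate(chain.atoms_by_residue):
        coords = np.array([a.coords for a in atoms])
        dmin = tree.query(coords)[0].min()
        labels[i] = 1 if dmin <= cutoff else 0
    return LabeledChain(chain=chain, labels=labels, cutoff=cutoff)


def filter_chains(
    chains: Iterable[ProteinChain],
    min_length: int = 40,
    max_resolution: float = 3.5,
) -> list[ProteinChain]:
    """Keep chains strictly longer than ``min_length`` residues with a
    resolution of ``max_resolution`` Å or better; chains without a recorded
    resolution are dropped and logged."""
    kept: list[ProteinChain] = []
    for chain in chains:
        if len(chain) <= min_length:
            continue
        if chain.resolution is None:
            logger.info("chain %s dropped: no resolution recorded", chain.chain_id)
            continue
        if chain.resolution <= max_resolution:
            kept.append(chain)
    return kept


def _global_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    """Fraction of identical columns over the global alignment length."""
    if not a or not b:
        return 0.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def _make_identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def reduce_redundancy(
    sequences: Sequence[tuple[str, str]],
    max_identity: float = 0.30,
) -> list[str]:
    """Greedy redundancy reduction at a pairwise-identity threshold.

    Sequences are visited by descending length (ties broken by id); a
    sequence whose global identity to an existing representative exceeds
    ``max_identity`` joins that representative's cluster, otherwise it
    founds a new one.  Returns the representative ids.
    """
    if not sequences:
        raise ValueError("sequences must be nonempty")
    aligner = _make_identity_aligner()
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    representatives: list[tuple[str, str]] = []
    for seq_id, seq in ordered:
        if not any(
            _global_identity(aligner, rep_seq, seq) > max_identity
            for _, rep_seq in representatives
        ):
            representatives.append((seq_id, seq))
    return [seq_id for seq_id, _ in representatives]


def write_labels_tsv(labeled: LabeledChain) -> str:
    """Render labels as TSV: chain_id, residue_index (1-based), residue
    number, amino acid, label."""
    lines = ["chain_id\tresidue_index\tresidue_number\taa\tlabel"]
    for i, (key, aa) in enumerate(zip(labeled.chain.residue_keys, labeled.chain.sequence)):
        num = f"{key[1]}{key[2]}" if key[2] else str(key[1])
        lines.append(
            f"{labeled.chain.chain_id}\t{i + 1}\t{num}\t{aa}\t{labeled.labels[i]}"
        )
    return "\n".join(lines) + "\n"
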