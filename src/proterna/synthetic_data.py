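"""Seed-deterministic synthetic fixtures with the statistical structure the
pipeline assumes.

Three generators mirror the three external data sources: toy protein–RNA
complexes with a planted interface span (so the 5 Å labeling geometry is
known by construction), homolog families with planted conserved blocks on a
mutated background, and profile matrices whose binding-residue columns carry
a tunable mean shift.  Writers emit the standard text formats (PDB, FASTA,
blastpgp-dialect PSSM, PSIPRED ``.ss2``) so every reader is exercised by its
own fixtures.

None of this attempts physically realistic protein geometry or a
phylogenetically realistic substitution model; it exists to give the
pipeline inputs whose ground truth is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from proterna.conservation_miner import HomologSet
from proterna.features import EncodingConfig, FeatureMatrix, encode_chain
from proterna.profiles import (
    PSSM,
    ProfileSet,
    SecondaryStructureProfile,
    normalize_pssm,
    write_pssm,
)
from proterna.structure_io import AtomRecord, ProteinChain, RNAComponent

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ONE2THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: PSSM rows (alphabet indices) carrying the planted binding signal; a small
#: fixed subset so the signal survives dilution across the 552-dim window
SIGNAL_ROWS = (0, 1, 2, 3, 4)


# ---------------------------------------------------------------------------
# toy complexes


@dataclass(frozen=True)
class SimComplexConfig:
    n_residues: int = 30
    interface_span: tuple[int, int] = (10, 15)  # 1-based inclusive; (1, 0) = empty
    rna_atoms: int = 20
    interface_distance: float = 3.0  # Å, must be < 5
    background_distance: float = 8.0  # Å, must be > 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.interface_distance < self.background_distance:
            raise ValueError("need 0 < interface_distance < background_distance")
        if not self.interface_distance < 5.0 < self.background_distance:
            raise ValueError("interface/background distances must straddle 5 Å")
        start, end = self.interface_span
        if end >= start and not (1 <= start and end <= self.n_residues):
            raise ValueError("interface_span outside the chain")


def simulate_complex(
    config: SimComplexConfig,
) -> tuple[ProteinChain, RNAComponent, np.ndarray]:
    """Build a toy complex whose binding labels are known by construction.

    RNA atoms sit in a unit ball at the origin.  Residues inside the
    interface span get one atom at exactly ``interface_distance`` from a
    randomly chosen RNA atom; all other atoms lie on a shell far enough out
    that their minimum distance to any RNA atom exceeds
    ``background_distance``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    start, end = config.interface_span

    directions = rng.normal(size=(config.rna_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    rna_coords = directions * rng.uniform(0, 1, size=(config.rna_atoms, 1))

    rna_atoms = [
        AtomRecord(
            element="P",
            name="P",
            coords=rna_coords[j],
            residue_key=("R", j + 1, ""),
        )
        for j in range(config.rna_atoms)
    ]
    rna = RNAComponent(chain_id="R", atoms=rna_atoms)

    # background shell: radius bg + 2 with <=0.5 jitter keeps every distance
    # to the unit RNA ball above bg
    shell = config.background_distance + 2.0
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    labels = np.zeros(n, dtype=int)
    atoms_by_residue: list[list[AtomRecord]] = []
    for i in range(n):
        key = ("A", i + 1, "")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        far = AtomRecord(
            element="C",
            name="CA",
            coords=u * (shell + rng.uniform(0, 0.5)),
            residue_key=key,
        )
        residue_atoms = [far]
        if start <= i + 1 <= end:
            labels[i] = 1
            anchor = rna_coords[rng.integers(config.rna_atoms)]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            residue_atoms.append(
                AtomRecord(
                    element="C",
                    name="CB",
                    coords=anchor + v * config.interface_distance,
                    residue_key=key,
                )
            )
        atoms_by_residue.append(residue_atoms)

    chain = ProteinChain(
        chain_id="A",
        sequence=sequence,
        residue_keys=[("A", i + 1, "") for i in range(n)],
        atoms_by_residue=atoms_by_residue,
        resolution=2.0,
    )
    return chain, rna, labels


def complex_to_pdb(chain: ProteinChain, rna: RNAComponent, resolution: float = 2.0) -> str:
    """Serialize a toy complex as minimal PDB text (one nucleotide per RNA
    atom) so the structure reader can be exercised on generated data."""
    lines = [f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS."]
    serial = 1
    for i, atoms in enumerate(chain.atoms_by_residue):
        resname = _ONE2THREE.get(chain.sequence[i], "UNK")
        for atom in atoms:
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:>5d} {atom.name:<4s} {resname:>3s} {chain.chain_id}"
                f"{i + 1:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    bases = "ACGU"
    for j, atom in enumerate(rna.atoms):
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:>5d} {atom.name:<4s}   {bases[j % 4]:>1s} {rna.chain_id}"
            f"{j + 1:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {atom.element:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# homolog families


@dataclass(frozen=True)
class SimFamilyConfig:
    query_length: int = 60
    n_homologs: int = 50
    background_identity: float = 0.3
    planted_blocks: tuple[tuple[int, int], ...] = ((10, 15), (31, 36))
    block_conservation: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_identity < 1:
            raise ValueError("background_identity must be in (0, 1)")
        if not 0 < self.block_conservation <= 1:
            raise ValueError("block_conservation must be in (0, 1]")
        last_end = 0
        for start, end in self.planted_blocks:
            if start <= last_end or end < start or end > self.query_length:
                raise ValueError("planted blocks must be disjoint and in range")
            last_end = end


def simulate_family(config: SimFamilyConfig) -> HomologSet:
    """Point-mutated homolog family with planted conserved blocks.

    Each homolog preserves a query position with probability
    ``block_conservation`` inside planted blocks and ``background_identity``
    elsewhere; mutated positions get a uniformly random different residue.
    """
    rng = np.random.default_rng(config.seed)
    query = "".join(rng.choice(list(AMINO_ACIDS), size=config.query_length))
    in_block = np.zeros(config.query_length, dtype=bool)
    for start, end in config.planted_blocks:
        in_block[start - 1 : end] = True
    keep_prob = np.where(in_block, config.block_conservation, config.background_identity)

    homologs: list[tuple[str, str, float]] = []
    for h in range(config.n_homologs):
        keep = rng.uniform(size=config.query_length) < keep_prob
        seq = list(query)
        for i in np.flatnonzero(~keep):
            choices = AMINO_ACIDS.replace(query[i], "")
            seq[i] = choices[rng.integers(len(choices))]
        identity = max(keep.mean(), 1.0 / config.query_length)
        homologs.append((f"hom{h:03d}", "".join(seq), float(identity)))
    return HomologSet(query=("query", query), homologs=homologs)


def family_to_fasta(homolog_set: HomologSet) -> str:
    """FASTA with the query first; identities recorded in the headers."""
    records = [f">{homolog_set.query[0]}\n{homolog_set.query[1]}"]
    for hid, seq, identity in homolog_set.homologs:
        records.append(f">{hid} identity={identity:.4f}\n{seq}")
    return "\n".join(records) + "\n"


# ---------------------------------------------------------------------------
# profile matrices


@dataclass(frozen=True)
class SimProfileConfig:
    chain_length: int = 60
    binding_labels: tuple[int, ...] = ()  # empty = no binding residues
    signal: float = 0.0  # mean shift of raw PSSM scores at binding residues
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binding_labels and len(self.binding_labels) != self.chain_length:
            raise ValueError("binding_labels must match chain_length")
        if self.signal < 0 or self.noise_sd <= 0:
            raise ValueError("signal must be >= 0 and noise_sd positive")


def _draw_raw_profiles(config: SimProfileConfig) -> tuple[str, np.ndarray, np.ndarray]:
    """Draw (sequence, integer raw PSSM, ss probabilities) for one chain."""
    rng = np.random.default_rng(config.seed)
    n = config.chain_length
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    raw = rng.normal(0.0, config.noise_sd, size=(20, n))
    if config.binding_labels:
        binding = np.asarray(config.binding_labels, dtype=bool)
        for row in SIGNAL_ROWS:
            raw[row, binding] += config.signal
    raw = np.round(raw)
    ss = rng.uniform(0.0, 1.0, size=(3, n))
    return sequence, raw, ss


def simulate_profiles(config: SimProfileConfig, chain_id: str = "sim") -> ProfileSet:
    """Profile bundle whose binding columns carry a planted mean shift on a
    fixed 5-row subset of the PSSM; secondary structure is uninformative."""
    _, raw, ss = _draw_raw_profiles(config)
    return ProfileSet(
        pssm_normalized=normalize_pssm(raw),
        ss=SecondaryStructureProfile(probs=ss),
        chain_id=chain_id,
    )


def profiles_to_files(config: SimProfileConfig) -> tuple[str, str]:
    """The same draw as :func:`simulate_profiles`, serialized as blastpgp
    ASCII PSSM text and PSIPRED ``.ss2`` text."""
    sequence, raw, ss = _draw_raw_profiles(config)
    pssm_text = write_pssm(PSSM(sequence=sequence, raw=raw))
    ss2_lines = ["# PSIPRED VFORMAT (synthetic)", ""]
    states = "CHE"
    for i in range(config.chain_length):
        p_h, p_e, p_c = ss[:, i]
        state = states[int(np.argmax([p_c, p_h, p_e]))]
        ss2_lines.append(
            f"{i + 1:>4d} {sequence[i]} {state}  {p_c:6.3f} {p_h:6.3f} {p_e:6.3f}"
        )
    return pssm_text, "\n".join(ss2_lines) + "\n"


def simulate_labeled_chains(
    n_chains: int = 20,
    chain_length: int = 60,
    signal: float = 0.0,
    noise_sd: float = 2.0,
    positive_fraction: float = 0.25,
    seed: int = 0,
    config: EncodingConfig = EncodingConfig(),
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Window-encoded chains with contiguous planted binding spans.

    Each chain carries one contiguous binding span covering roughly
    ``positive_fraction`` of its residues — mimicking the spatial clustering
    of real interfaces and giving adjacent residues the overlapping-window
    correlation that distinguishes sequence-based from window-based
    cross-validation.  Returns ``(chain_id, X, y)`` triples ready for
    :func:`proterna.evaluation.cross_validate`.
    """
    rng = np.random.default_rng(seed)
    span_len = max(1, int(round(positive_fraction * chain_length)))
    dataset = []
    for c in range(n_chains):
        start = int(rng.integers(0, chain_length - span_len + 1))
        labels = np.zeros(chain_length, dtype=int)
        labels[start : start + span_len] = 1
        profile_config = SimProfileConfig(
            chain_length=chain_length,
            binding_labels=tuple(labels.tolist()),
            signal=signal,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        chain_id = f"chain{c:03d}"
        profiles = simulate_profiles(profile_config, chain_id=chain_id)
        X = encode_chain(profiles, config).rows
        dataset.append((chain_id, X, labels))
    return dataset
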