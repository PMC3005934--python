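import numpy as np
import pytest

from proterna.profiles import (
    PSSM,
    ProfileSet,
    SecondaryStructureProfile,
    normalize_pssm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20100)


@pytest.fixture
def minimal_pdb() -> str:
    """Hand-written complex: 3-residue protein chain A, 1-nucleotide RNA
    chain R, one hydrogen that readers must drop."""
    return "\n".join(
        [
            "REMARK   2 RESOLUTION.    2.00 ANGSTROMS.",
            "ATOM      1 N    ALA A   1       0.000   0.000  10.000  1.00  0.00           N",
            "ATOM      2 CA   ALA A   1       1.000   0.000  10.000  1.00  0.00           C",
            "ATOM      3 H    ALA A   1       1.500   0.500  10.000  1.00  0.00           H",
            "ATOM      4 CA   GLY A   2       4.000   0.000  10.000  1.00  0.00           C",
            "ATOM      5 CA   SER A   3       8.000   0.000  10.000  1.00  0.00           C",
            "TER",
            "ATOM      6 P      A R   1       0.000   0.000   0.000  1.00  0.00           P",
            "ATOM      7 C4'    A R   1       1.000   1.000   0.000  1.00  0.00           C",
            "END",
        ]
    ) + "\n"


@pytest.fixture
def altloc_pdb() -> str:
    """One atom in two alternate locations: A at occupancy 0.6, B at 0.4."""
    return "\n".join(
        [
            "ATOM      1 CA  AALA A   1       0.000   0.000   0.000  0.60  0.00           C",
            "ATOM      2 CA  BALA A   1       0.500   0.000   0.000  0.40  0.00           C",
            "TER",
            "ATOM      3 P      A R   1       5.000   0.000   0.000  1.00  0.00           P",
            "END",
        ]
    ) + "\n"


@pytest.fixture
def pssm_3res() -> str:
    """Hand-written 3-residue blastpgp-dialect PSSM (log-odds + frequency
    halves); log-odds values are row i = [i, i+1, ..., i+19] offsets."""
    header = (
        "\nLast position-specific scoring matrix computed\n"
        "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V\n"
    )
    lines = [header.rstrip("\n")]
    for i, aa in enumerate("MKL", start=1):
        scores = " ".join(f"{i + j - 10:>3d}" for j in range(20))
        freqs = " ".join("5" for _ in range(20))
        lines.append(f"{i:>5d} {aa}  {scores}  {freqs}  0.50 0.10")
    lines.append("")
    lines.append("                      K         Lambda")
    return "\n".join(lines) + "\n"


@pytest.fixture
def ss2_5res() -> str:
    return "\n".join(
        [
            "# PSIPRED VFORMAT (PSIPRED V4.0)",
            "",
            "   1 M C   0.800  0.150  0.050",
            "   2 K H   0.100  0.850  0.050",
            "   3 L H   0.200  0.700  0.100",
            "   4 V E   0.250  0.050  0.700",
            "   5 A C   0.900  0.050  0.050",
        ]
    ) + "\n"


def make_profile_set(n: int, seed: int = 0, chain_id: str = "t") -> ProfileSet:
    """Random but reproducible profile bundle of length n."""
    rng = np.random.default_rng(seed)
    raw = rng.integers(-10, 11, size=(20, n))
    ss = SecondaryStructureProfile(probs=rng.uniform(0, 1, size=(3, n)))
    return ProfileSet(pssm_normalized=normalize_pssm(raw), ss=ss, chain_id=chain_id)


@pytest.fixture
def profile_set_60() -> ProfileSet:
    return make_profile_set(60, seed=7)
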