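import random
import textwrap

import pytest

from degronkit.motif_registry import (CompiledMotif, DegronMotif, LocationClass,
                                      MotifSet)
from degronkit.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: random.Random, min_len=5, max_len=60) -> str:
    return "".join(rng.choice(AA) for _ in range(rng.randint(min_len, max_len)))


def make_motif(motif_id, pattern, location=LocationClass.INTERNAL):
    return DegronMotif(motif_id=motif_id, name=motif_id, pattern=pattern,
                       location_class=location, compiled=CompiledMotif(pattern))


def make_motif_set(*motifs):
    return MotifSet(motifs=tuple(motifs), provenance="test")


@pytest.fixture
def rng():
    return random.Random(20240)


def pdb_text(sequence, b_factors=None, chain="A", start_index=1, model=1):
    """Minimal single-atom-per-residue PDB text for fixtures."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    if b_factors is None:
        b_factors = [90.0] * len(sequence)
    lines = [f"MODEL     {model:4d}"]
    serial = 1
    for i, (aa, b) in enumerate(zip(sequence, b_factors)):
        resseq = start_index + i
        x = 1.5 * i
        lines.append(
            f"ATOM  {serial:5d}  CA  {three[aa]} {chain}{resseq:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}           C")
        serial += 1
    lines += ["ENDMDL", "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_pdb(tmp_path):
    def _write(sequence, name="model", **kwargs):
        path = tmp_path / f"{name}.pdb"
        path.write_text(pdb_text(sequence, **kwargs))
        return path
    return _write


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for pid, seq in entries:
                fh.write(f">{pid}\n")
                fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
        return path
    return _write


@pytest.fixture
def toy_record():
    return ProteinRecord(id="toy", sequence="MAKAALKENPGG")
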