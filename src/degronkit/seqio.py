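"""Query input handling: FASTA/PDB reading, validation and Met variants.

A query is either a plain protein sequence (:class:`ProteinRecord`) or a
monomeric structure (:class:`StructureModel`) whose B-factor column may carry
per-residue pLDDT/LDDT confidence from a predicted model. Structures must
contain a single model and a single chain with residues numbered continuously
from 1; sequences must consist of the 20 canonical amino acids and stay below
the 40 000-residue query limit.

Positions are 1-based and inclusive throughout the package, always expressed
in the frame of the sequence as given; results computed on the
initiator-Met-cleaved variant are mapped back by a +1 offset.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from ._aa import AMBIGUOUS_AA, CANONICAL_SET

MAX_QUERY_LENGTH = 40_000          # exclusive upper bound on sequence length
MAX_STRUCTURE_BYTES = 5 * 1024 * 1024


class Origin(str, Enum):
    FASTA = "fasta"
    PDB = "pdb"
    ACCESSION = "accession"


class MetVariant(str, Enum):
    AS_GIVEN = "as_given"
    MET_CLEAVED = "met_cleaved"


class FailureCode(str, Enum):
    TOO_LONG = "too_long"
    NON_CANONICAL = "non_canonical"
    MULTI_CHAIN = "multi_chain"
    MULTI_MODEL = "multi_model"
    DISCONTINUOUS_NUMBERING = "discontinuous_numbering"
    FILE_TOO_LARGE = "file_too_large"
    EMPTY = "empty"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence query."""

    id: str
    sequence: str
    description: str = ""
    origin: Origin = Origin.FASTA
    met_variant: MetVariant = MetVariant.AS_GIVEN

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Residue:
    index: int
    aa: str
    b_factor: float
    atoms: tuple = ()   # tuple of (name, x, y, z)


@dataclass(frozen=True)
class StructureModel:
    """A validated single-model, single-chain protein structure."""

    record: ProteinRecord
    residues: tuple

    def b_factors(self) -> list:
        return [r.b_factor for r in self.residues]


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    failures: tuple = ()

    @classmethod
    def from_failures(cls, failures: Iterable) -> "ValidationResult":
        failures = tuple(failures)
        return cls(ok=not failures, failures=failures)


@dataclass(frozen=True)
class ValidationLimits:
    """Query constraints; defaults mirror the server-style limits."""

    max_length: int = MAX_QUERY_LENGTH
    allow_x: bool = False
    max_structure_bytes: int = MAX_STRUCTURE_BYTES


class InputError(ValueError):
    """Raised for inputs that cannot be represented at all."""


def read_fasta(path) -> list:
    """Read all records from a FASTA file, in file order, upper-cased.

    Records are *not* validated here; run :func:`validate_query` afterwards.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"zero-length entry {rec.id!r} in {path}")
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description,
                          origin=Origin.FASTA)
        )
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


class StructureError(InputError):
    def __init__(self, failures):
        self.failures = tuple(failures)
        super().__init__("; ".join(f"{c.value}: {m}" for c, m in self.failures))


def read_structure(path, limits: ValidationLimits = ValidationLimits()) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Requirements: one model, one chain, protein residues only (HETATM and
    waters are ignored), residue numbering continuous from 1, file below the
    size limit. The per-residue B-factor (first atom of each residue) is kept
    verbatim so predicted models can carry pLDDT/LDDT.
    """
    path = Path(path)
    failures = []
    if path.stat().st_size > limits.max_structure_bytes:
        failures.append((FailureCode.FILE_TOO_LARGE,
                         f"{path} exceeds {limits.max_structure_bytes} bytes"))
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, os.fspath(path))
    models = list(structure)
    if not models:
        raise StructureError([(FailureCode.EMPTY, "no ATOM records")])
    if len(models) > 1:
        failures.append((FailureCode.MULTI_MODEL, f"{len(models)} models found"))
    chains = list(models[0])
    if len(chains) > 1:
        ids = ",".join(c.id for c in chains)
        failures.append((FailureCode.MULTI_CHAIN, f"chains {ids} found"))
    if failures:
        raise StructureError(failures)

    residues = []
    for res in chains[0]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():          # HETATM / water: ignored
            continue
        aa = seq1(res.get_resname())
        if aa == "X" or aa not in CANONICAL_SET:
            raise StructureError(
                [(FailureCode.NON_CANONICAL,
                  f"non-protein or non-canonical residue {res.get_resname()} "
                  f"at {resseq}")])
        atoms = tuple(
            (atom.get_name(), *map(float, atom.get_coord()))
            for atom in res.get_atoms()
        )
        b = float(next(res.get_atoms()).get_bfactor())
        residues.append(Residue(index=resseq, aa=aa, b_factor=b, atoms=atoms))

    if not residues:
        raise StructureError([(FailureCode.EMPTY, "no protein residues")])
    indices = [r.index for r in residues]
    if indices != list(range(1, len(residues) + 1)):
        raise StructureError(
            [(FailureCode.DISCONTINUOUS_NUMBERING,
              f"residue numbering {indices[0]}..{indices[-1]} is not "
              f"continuous from 1")])

    sequence = "".join(r.aa for r in residues)
    record = ProteinRecord(id=path.stem, sequence=sequence, origin=Origin.PDB)
    return StructureModel(record=record, residues=tuple(residues))


def validate_query(record_or_model: Union[ProteinRecord, StructureModel],
                   limits: ValidationLimits = ValidationLimits()) -> ValidationResult:
    """Collect *all* constraint violations of a query (never fail-fast)."""
    if isinstance(record_or_model, StructureModel):
        record = record_or_model.record
    else:
        record = record_or_model
    failures = []
    if not record.sequence:
        failures.append((FailureCode.EMPTY, "empty sequence"))
    if len(record.sequence) >= limits.max_length:
        failures.append((FailureCode.TOO_LONG,
                         f"length {len(record.sequence)} >= {limits.max_length}"))
    allowed = CANONICAL_SET | ({"X"} if limits.allow_x else set())
    bad = sorted({a for a in record.sequence if a not in allowed})
    if bad:
        kind = "ambiguous" if set(bad) <= AMBIGUOUS_AA else "unknown"
        failures.append((FailureCode.NON_CANONICAL,
                         f"{kind} residue letter(s): {','.join(bad)}"))
    if isinstance(record_or_model, StructureModel):
        model = record_or_model
        if "".join(r.aa for r in model.residues) != record.sequence:
            failures.append((FailureCode.NON_CANONICAL,
                             "residues do not match record sequence"))
        if [r.index for r in model.residues] != list(range(1, len(model.residues) + 1)):
            failures.append((FailureCode.DISCONTINUOUS_NUMBERING,
                             "residue numbering not continuous from 1"))
    return ValidationResult.from_failures(failures)


def met_variants(record: ProteinRecord) -> list:
    """Return the query and, when applicable, its initiator-Met-cleaved form.

    N-terminal methionine excision exposes residue 2 as a new N terminus, so
    scanning both forms covers co-translational Met processing. Sequences not
    starting with M, and the degenerate single-residue "M", yield only the
    as-given form.
    """
    variants = [record]
    if record.sequence.startswith("M") and len(record.sequence) >= 2:
        variants.append(
            replace(record, sequence=record.sequence[1:],
                    met_variant=MetVariant.MET_CLEAVED)
        )
    return variants


def fragment_offset(record: ProteinRecord) -> int:
    """Offset mapping variant-frame positions to the as-given frame."""
    return 1 if record.met_variant is MetVariant.MET_CLEAVED else 0
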