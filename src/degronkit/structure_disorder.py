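"""Per-residue structural context: secondary structure, RSA, disorder, IDRs.

Secondary structure and absolute solvent accessibility come from an external
DSSP-style adapter (never re-implemented here); absolute ASA is normalized to
relative solvent accessibility (RSA) with the Sander per-residue maxima,
clamped to [0, 1].

Disorder is called in one of two modes:

``structure_plddt``
    the PDB B-factor column is read as pLDDT/LDDT confidence; a residue is
    disordered when its score falls *below* the threshold (default 70).
``sequence``
    a per-residue score in [0, 1] from a sequence-based predictor; a residue
    is disordered when its score rises *above* the threshold (default 0.5).
    If no external predictor adapter is configured, a built-in windowed
    hydropathy/net-charge heuristic (FoldIndex-style, window 21, rescaled to
    [0, 1]) is used and labelled as such in outputs.

Intrinsically disordered regions (IDRs) are maximal runs of disordered
residues meeting a configurable minimum length (default 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, List, Optional, Sequence, Union

from ._aa import KYTE_DOOLITTLE, SANDER_MAX_ASA
from .seqio import ProteinRecord, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_PLDDT_THRESHOLD = 70.0
DEFAULT_SEQUENCE_THRESHOLD = 0.5
DEFAULT_MIN_IDR_LENGTH = 10
_FOLDINDEX_WINDOW = 21


class DisorderMode(str, Enum):
    STRUCTURE_PLDDT = "structure_plddt"
    SEQUENCE = "sequence"


@dataclass(frozen=True)
class ResidueContext:
    position: int
    aa: str
    ss: str = "-"                 # DSSP 8-class code, '-' when unknown
    asa: Optional[float] = None   # absolute ASA in A^2, None when unavailable
    rsa: Optional[float] = None
    disorder_score: float = 0.0
    disordered: bool = False


@dataclass(frozen=True)
class IDR:
    start: int
    end: int
    mean_disorder: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DisorderProfile:
    mode: DisorderMode
    threshold: float
    scores: tuple
    flags: tuple
    method: str = ""


def residue_rsa(aa: str, asa: float) -> float:
    """Relative solvent accessibility: ASA over the Sander maximum, clamped."""
    if aa not in SANDER_MAX_ASA:
        raise ValueError(f"non-canonical residue {aa!r}")
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    return min(1.0, asa / SANDER_MAX_ASA[aa])


def _foldindex_scores(sequence: str, window: int = _FOLDINDEX_WINDOW) -> List[float]:
    # FoldIndex-style: 2.785*<H> - |<q>| - 1.151 over a sliding window, with
    # hydropathy rescaled to [0,1]; negative values indicate disorder. The
    # raw index is mapped to a [0,1] disorder score via 0.5 - index, clamped,
    # so the 0.5 decision boundary coincides with index = 0.
    charge = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}
    L = len(sequence)
    half = window // 2
    scores = []
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        win = sequence[lo:hi]
        h = sum((KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in win) / len(win)
        q = sum(charge.get(a, 0.0) for a in win) / len(win)
        index = 2.785 * h - abs(q) - 1.151
        scores.append(min(1.0, max(0.0, 0.5 - index)))
    return scores


def disorder_profile(
    query: Union[StructureModel, ProteinRecord],
    mode: Union[DisorderMode, str] = DisorderMode.SEQUENCE,
    threshold: Optional[float] = None,
    sequence_predictor: Optional[Callable] = None,
) -> DisorderProfile:
    """Per-residue disorder scores and flags for a query.

    ``sequence_predictor``, when given, is a callable ``seq -> scores`` (an
    external predictor adapter, e.g. an IUPred-style tool wrapper); otherwise
    the built-in heuristic is used in sequence mode.
    """
    mode = DisorderMode(mode)
    if mode is DisorderMode.STRUCTURE_PLDDT:
        if not isinstance(query, StructureModel):
            raise ValueError("structure_plddt mode requires a StructureModel")
        thr = DEFAULT_PLDDT_THRESHOLD if threshold is None else threshold
        scores = tuple(query.b_factors())
        if scores and all(s == 0.0 for s in scores):
            warnings.warn("all B-factors are zero: the column likely does not "
                          "carry pLDDT/LDDT scores", stacklevel=2)
        flags = tuple(s < thr for s in scores)
        return DisorderProfile(mode, thr, scores, flags, method="plddt_bfactor")

    record = query.record if isinstance(query, StructureModel) else query
    thr = DEFAULT_SEQUENCE_THRESHOLD if threshold is None else threshold
    if sequence_predictor is not None:
        scores = tuple(float(s) for s in sequence_predictor(record.sequence))
        if len(scores) != len(record.sequence):
            raise ValueError("sequence predictor returned "
                             f"{len(scores)} scores for {len(record.sequence)} residues")
        method = "external_adapter"
    else:
        scores = tuple(_foldindex_scores(record.sequence))
        method = "builtin_hydropathy_charge_heuristic"
    flags = tuple(s > thr for s in scores)
    return DisorderProfile(mode, thr, scores, flags, method=method)


def segment_idrs(profile: DisorderProfile,
                 min_len: int = DEFAULT_MIN_IDR_LENGTH) -> List[IDR]:
    """Maximal runs of disordered residues with length >= ``min_len``."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    idrs = []
    start = None
    flags = list(profile.flags) + [False]      # sentinel closes a final run
    for i, flag in enumerate(flags):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                run = profile.scores[start:i]
                idrs.append(IDR(start=start + 1, end=i,
                                mean_disorder=sum(run) / len(run)))
            start = None
    return idrs


def secondary_structure(model: StructureModel,
                        adapter: Optional[Callable] = None):
    """Secondary structure + ASA via an external DSSP-style adapter.

    ``adapter`` is a callable ``model -> list of (ss_code, asa)`` of length N
    (e.g. a mkdssp wrapper). Without an adapter, or if it fails, ss degrades
    to '-' and ASA to None for every residue — a warning is logged, the run
    continues.
    """
    n = len(model.residues)
    if adapter is None:
        logger.warning("no secondary-structure adapter configured; "
                       "ss/ASA reported as unavailable")
        return [("-", None)] * n
    try:
        out = list(adapter(model))
    except Exception as exc:       # adapter failure degrades, never aborts
        logger.warning("secondary-structure adapter failed (%s); "
                       "ss/ASA reported as unavailable", exc)
        return [("-", None)] * n
    if len(out) != n:
        raise ValueError(f"length_mismatch: adapter returned {len(out)} "
                         f"entries for {n} residues")
    return [(str(ss), None if asa is None else float(asa)) for ss, asa in out]


def residue_contexts(
    query: Union[StructureModel, ProteinRecord],
    profile: DisorderProfile,
    ss_asa: Optional[Sequence] = None,
) -> List[ResidueContext]:
    """Combine sequence, disorder and (optional) ss/ASA into per-residue rows."""
    record = query.record if isinstance(query, StructureModel) else query
    seq = record.sequence
    if len(profile.scores) != len(seq):
        raise ValueError("disorder profile length does not match sequence")
    if ss_asa is None:
        ss_asa = [("-", None)] * len(seq)
    if len(ss_asa) != len(seq):
        raise ValueError("length_mismatch between ss/ASA and sequence")
    rows = []
    for i, aa in enumerate(seq):
        ss, asa = ss_asa[i]
        rsa = None if asa is None else residue_rsa(aa, asa)
        rows.append(ResidueContext(
            position=i + 1, aa=aa, ss=ss, asa=asa, rsa=rsa,
            disorder_score=profile.scores[i], disordered=profile.flags[i]))
    return rows
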