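"""Degron motif scanning over both initiator-Met variants.

The scanner enforces location semantics: N-terminal motifs are tested only
anchored at the first residue of the active Met variant, C-terminal motifs
only anchored at the last residue, internal motifs at every position.
Matches are reported in full-length (as-given) coordinates; hits found on
the Met-cleaved variant are shifted by +1 and flagged.

Also provides the terminal hydrophobicity summary (Gravy over the terminal
window, default 15 residues — hydrophobic termini are recognized by several
N-/C-degron E3 ligases) and the Arg/N-end-rule classification of an
N-terminal residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Mapping, Optional

from ._aa import CANONICAL_SET, N_END_RULE_CLASSES, gravy
from .motif_registry import DegronMotif, LocationClass, MotifSet
from .seqio import MetVariant, ProteinRecord, fragment_offset, met_variants

DEFAULT_GRAVY_WINDOW = 15


class Terminus(str, Enum):
    N = "N"
    C = "C"
    NONE = "none"


class NEndClass(str, Enum):
    TYPE1_PRIMARY = "type1_primary"
    TYPE2_PRIMARY = "type2_primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"
    STABILIZING = "stabilizing"


@dataclass(frozen=True)
class DegronMatch:
    motif_id: str
    start: int                      # 1-based inclusive, full-length frame
    end: int
    matched_seq: str
    location_class: LocationClass
    met_variant: MetVariant
    terminus: Terminus


@dataclass(frozen=True)
class TerminalSummary:
    n_gravy: float
    c_gravy: float
    window_w: int
    n_end_class: Mapping            # MetVariant -> NEndClass


@dataclass(frozen=True)
class ScanParams:
    include_met_variants: bool = True


_TERMINUS_OF = {
    LocationClass.N_TERMINAL: Terminus.N,
    LocationClass.C_TERMINAL: Terminus.C,
    LocationClass.INTERNAL: Terminus.NONE,
}


def scan_degrons(record: ProteinRecord, motifs: MotifSet,
                 params: ScanParams = ScanParams()) -> List[DegronMatch]:
    """Screen a protein (both Met variants) for degron motifs.

    Returns matches deduplicated on (motif_id, start, end, met_variant), in
    deterministic (start, end, motif_id, met_variant) order.
    """
    variants = met_variants(record) if params.include_met_variants else [record]
    seen, out = set(), []
    for variant in variants:
        seq = variant.sequence
        offset = fragment_offset(variant)
        for motif in motifs:
            matcher = motif.matcher()
            if motif.location_class is LocationClass.N_TERMINAL:
                spans = matcher.matches_at_start(seq)
            elif motif.location_class is LocationClass.C_TERMINAL:
                spans = matcher.matches_at_end(seq)
            else:
                spans = matcher.find_all(seq)
            for s, e in spans:
                key = (motif.motif_id, s + offset, e + offset, variant.met_variant)
                if key in seen:
                    continue
                seen.add(key)
                out.append(DegronMatch(
                    motif_id=motif.motif_id, start=s + offset, end=e + offset,
                    matched_seq=seq[s - 1:e],
                    location_class=motif.location_class,
                    met_variant=variant.met_variant,
                    terminus=_TERMINUS_OF[motif.location_class]))
    out.sort(key=lambda m: (m.start, m.end, m.motif_id, m.met_variant.value))
    return out


def terminal_gravy(record: ProteinRecord,
                   window_w: int = DEFAULT_GRAVY_WINDOW) -> TerminalSummary:
    """Mean Kyte-Doolittle hydropathy of the first/last ``window_w`` residues.

    Sequences shorter than the window use all available residues (digestion
    fragments can be short).
    """
    seq = record.sequence
    w = min(window_w, len(seq))
    n_end = {}
    for variant in met_variants(record):
        n_end[variant.met_variant] = n_end_rule_class(variant.sequence[0])
    return TerminalSummary(
        n_gravy=gravy(seq[:w]), c_gravy=gravy(seq[-w:]),
        window_w=window_w, n_end_class=n_end)


def n_end_rule_class(residue: str,
                     table: Optional[Mapping] = None) -> NEndClass:
    """Classify an N-terminal residue under the Arg/N-degron pathway.

    Default table: type-1 primary R,K,H; type-2 primary F,W,Y,L,I; secondary
    D,E; tertiary N,Q,C; everything else stabilizing. A user table mapping
    class name -> residue set overrides the default.
    """
    if residue not in CANONICAL_SET:
        raise ValueError(f"non-canonical residue {residue!r}")
    table = table if table is not None else N_END_RULE_CLASSES
    for cls_name, members in table.items():
        if residue in members:
            return NEndClass(cls_name)
    return NEndClass.STABILIZING
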