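"""In-silico proteolysis: cleavage rules, digestion, neo-terminus screening.

Cleavage specificity is expressed as context patterns over the protease
subsites around the scissile bond (P4..P1 | P1'..P2' in Schechter-Berger
notation). A pattern is a string of position tokens — literal residue,
``[..]`` class, ``[^..]`` negated class, or ``.`` (any canonical residue) —
with exactly one ``|`` marking the scissile bond. A rule may list several
site patterns (their matches are unioned) and exception patterns that veto a
cut. A token never matches beyond the chain: a rule that requires context
outside the sequence cannot fire at that bond, mirroring how lookaround-based
rule engines behave at chain termini.

The built-in registry covers 35 proteolytic enzymes with the published
PeptideCutter specificities. Digestion products are re-screened for degrons
at their *newly created* termini: the neo-N residue's Arg/N-end-rule class,
anchored N-/C-terminal motif hits, terminal hydrophobicity and, optionally,
predicted terminal-peptide stability (PSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from ._aa import CANONICAL_SET
from .degron_scanner import (DegronMatch, NEndClass, ScanParams, TerminalSummary,
                             n_end_rule_class, scan_degrons, terminal_gravy)
from .motif_registry import MotifSet
from .seqio import MetVariant, Origin, ProteinRecord


class RulePatternError(ValueError):
    pass


class UnknownEnzymeError(KeyError):
    pass


def _parse_side(side: str, pattern: str) -> List[frozenset]:
    tokens, i = [], 0
    while i < len(side):
        ch = side[i]
        if ch == "[":
            j = side.find("]", i)
            if j < 0:
                raise RulePatternError(f"unclosed class in {pattern!r}")
            body = side[i + 1:j]
            negate = body.startswith("^")
            if negate:
                body = body[1:]
            members = frozenset(body)
            if not members <= CANONICAL_SET:
                raise RulePatternError(f"non-canonical letters in class of {pattern!r}")
            tokens.append(frozenset(CANONICAL_SET) - members if negate else members)
            i = j + 1
        elif ch == ".":
            tokens.append(frozenset(CANONICAL_SET))
            i += 1
        elif ch in CANONICAL_SET:
            tokens.append(frozenset(ch))
            i += 1
        else:
            raise RulePatternError(f"bad token {ch!r} in cleavage pattern {pattern!r}")
    return tokens


class _BondPattern:
    """A compiled subsite-context pattern with one scissile-bond marker."""

    def __init__(self, pattern: str):
        if pattern.count("|") != 1:
            raise RulePatternError(
                f"cleavage pattern {pattern!r} must mark exactly one scissile "
                f"bond with '|'")
        before, after = pattern.split("|")
        self.pattern = pattern
        self.before = _parse_side(before, pattern)   # ends at P1
        self.after = _parse_side(after, pattern)     # starts at P1'
        if not self.before and not self.after:
            raise RulePatternError(f"empty cleavage pattern {pattern!r}")

    def matches_bond(self, seq: str, p: int) -> bool:
        """True if the bond between residues p and p+1 (1-based) matches."""
        for k, tok in enumerate(reversed(self.before)):   # P1, P2, ...
            idx = p - 1 - k
            if idx < 0 or seq[idx] not in tok:
                return False
        for k, tok in enumerate(self.after):              # P1', P2', ...
            idx = p + k
            if idx >= len(seq) or seq[idx] not in tok:
                return False
        return True


@dataclass(frozen=True)
class CleavageRule:
    enzyme: str
    sites: tuple                   # tuple of pattern strings
    exceptions: tuple = ()
    source: str = "PeptideCutter (ExPASy) published specificity"

    def compiled(self) -> Tuple[list, list]:
        return ([_BondPattern(s) for s in self.sites],
                [_BondPattern(e) for e in self.exceptions])

    def cut_positions(self, seq: str) -> List[int]:
        sites, vetoes = self.compiled()
        out = []
        for p in range(1, len(seq)):
            if any(s.matches_bond(seq, p) for s in sites) and \
               not any(v.matches_bond(seq, p) for v in vetoes):
                out.append(p)
        return out


class CleavageSource(str, Enum):
    USER_MOTIF = "user_motif"
    USER_SITE = "user_site"
    SITE_TABLE = "site_table"
    RULE = "rule"


@dataclass(frozen=True)
class CleavageEvent:
    position: int                  # bond position|position+1 is cleaved
    source: CleavageSource
    enzyme: Optional[str] = None


@dataclass(frozen=True)
class Fragment:
    parent_id: str
    start: int                     # 1-based inclusive, parent coordinates
    end: int
    sequence: str
    neo_n: bool
    neo_c: bool

    @property
    def id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class NeoDegronReport:
    fragment: Fragment
    neo_n_class: Optional[NEndClass]
    neo_n_matches: tuple           # DegronMatch in fragment coordinates
    neo_c_matches: tuple
    terminal: TerminalSummary
    parent_positions: dict        # match -> (parent_start, parent_end)
    psi: Optional[dict] = None    # terminus label -> PSIPrediction


# --- built-in enzyme registry ---------------------------------------------

_BUILTIN_RULES = [
    ("Arg-C proteinase", ["R|"], []),
    ("Asp-N endopeptidase", ["|D"], []),
    ("BNPS-Skatole", ["W|"], []),
    ("Caspase 1", ["[FWYL].[HAT]D|[^PEDQKR]"], []),
    ("Caspase 2", ["DVAD|[^PEDQKR]"], []),
    ("Caspase 3", ["DMQD|[^PEDQKR]"], []),
    ("Caspase 4", ["LEVD|[^PEDQKR]"], []),
    ("Caspase 5", ["[LW]EHD|"], []),
    ("Caspase 6", ["VE[HI]D|[^PEDQKR]"], []),
    ("Caspase 7", ["DEVD|[^PEDQKR]"], []),
    ("Caspase 8", ["[IL]ETD|[^PEDQKR]"], []),
    ("Caspase 9", ["LEHD|"], []),
    ("Caspase 10", ["IEAD|"], []),
    ("Chymotrypsin high specificity", ["[FY]|[^P]", "W|[^MP]"], []),
    ("Chymotrypsin low specificity",
     ["[FLY]|[^P]", "W|[^MP]", "M|[^PY]", "H|[^DMPW]"], []),
    ("Clostripain", ["R|"], []),
    ("CNBr", ["M|"], []),
    ("Enterokinase", ["[DE][DE][DE]K|"], []),
    ("Factor Xa", ["[AFGILTVM][DE]GR|"], []),
    ("Formic acid", ["D|"], []),
    ("Glutamyl endopeptidase", ["E|"], []),
    ("Granzyme B", ["IEPD|"], []),
    ("Hydroxylamine", ["N|G"], []),
    ("Iodosobenzoic acid", ["W|"], []),
    ("LysC", ["K|"], []),
    ("LysN", ["|K"], []),
    ("NTCB (2-nitro-5-thiocyanobenzoic acid)", ["|C"], []),
    ("Pepsin (pH 1.3)",
     ["[^HKR][^P][^R]|[FL][^P]", "[^HKR][^P][FL]|.[^P]"], []),
    ("Pepsin (pH >2)",
     ["[^HKR][^P][^R]|[FLWY][^P]", "[^HKR][^P][FLWY]|.[^P]"], []),
    ("Proline-endopeptidase", ["[HKR]P|[^P]"], []),
    ("Proteinase K", ["[AEFILTVWY]|"], []),
    ("Staphylococcal peptidase I", ["[^E]E|"], []),
    ("Thermolysin", ["[^DE]|[AFILMV][^P]"], []),
    ("Thrombin", ["GR|G", "[AFGILTVM][AFGILTVWA]PR|[^DE][^DE]"], []),
    ("Trypsin", ["[KR]|[^P]", "WK|P", "MR|P"],
     ["[CD]K|D", "CK|[HY]", "CR|K", "RR|[HR]"]),
]


def builtin_rules() -> List[CleavageRule]:
    """The 35 built-in protease rules (PeptideCutter-compatible semantics)."""
    return [CleavageRule(enzyme=name, sites=tuple(sites),
                         exceptions=tuple(exc))
            for name, sites, exc in _BUILTIN_RULES]


def get_rule(enzyme: str) -> CleavageRule:
    for rule in builtin_rules():
        if rule.enzyme.lower() == enzyme.lower():
            return rule
    raise UnknownEnzymeError(
        f"unknown_enzyme: {enzyme!r}; known enzymes: "
        + ", ".join(r.enzyme for r in builtin_rules()))


# --- site discovery and digestion ------------------------------------------

def find_cleavage_sites(
    record: ProteinRecord,
    rule: Optional[Union[CleavageRule, str]] = None,
    motif: Optional[str] = None,
    positions: Optional[Iterable[int]] = None,
    site_rows: Optional[pd.DataFrame] = None,
    skip_non_physiological: bool = True,
) -> List[CleavageEvent]:
    """Resolve a cleavage specification into sorted, unique bond events.

    Exactly one of ``rule`` (a :class:`CleavageRule` or enzyme name),
    ``motif`` (a user context pattern with a ``|`` bond marker),
    ``positions`` (explicit bond positions) or ``site_rows`` (a validated
    cleavage-site table) must be given.
    """
    given = [x is not None for x in (rule, motif, positions, site_rows)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of rule, motif, positions, site_rows")
    L = len(record.sequence)
    events: List[CleavageEvent] = []
    if rule is not None:
        if isinstance(rule, str):
            rule = get_rule(rule)
        events = [CleavageEvent(p, CleavageSource.RULE, rule.enzyme)
                  for p in rule.cut_positions(record.sequence)]
    elif motif is not None:
        if "|" not in motif:
            raise RulePatternError(
                f"user cleavage motif {motif!r} never marks a bond: add '|' "
                f"at the scissile position")
        pat = _BondPattern(motif)
        events = [CleavageEvent(p, CleavageSource.USER_MOTIF)
                  for p in range(1, L) if pat.matches_bond(record.sequence, p)]
    elif positions is not None:
        for p in positions:
            p = int(p)
            if not 1 <= p <= L - 1:
                raise ValueError(f"cleavage position {p} outside 1..{L - 1}")
            events.append(CleavageEvent(p, CleavageSource.USER_SITE))
    else:
        required = ["protein_id", "position"]
        missing = [c for c in required if c not in site_rows.columns]
        if missing:
            raise ValueError(f"site table missing column(s) {','.join(missing)}")
        for _, row in site_rows.iterrows():
            if str(row.get("protein_id", "")) != record.id:
                continue
            if skip_non_physiological and "physiological" in site_rows.columns:
                phys = str(row["physiological"]).strip().lower()
                if phys in ("false", "0", "no", "n"):
                    continue
            p = int(row["position"])
            if not 1 <= p <= L - 1:
                raise ValueError(f"site-table position {p} outside 1..{L - 1}")
            events.append(CleavageEvent(p, CleavageSource.SITE_TABLE,
                                        row.get("enzyme") or None))
    uniq = {}
    for ev in events:
        uniq.setdefault(ev.position, ev)
    return [uniq[p] for p in sorted(uniq)]


class DigestMode(str, Enum):
    FULL = "full"
    SINGLE_SITE = "single_site"


def digest(record: ProteinRecord, events: Sequence[CleavageEvent],
           mode: Union[DigestMode, str] = DigestMode.FULL) -> List[Fragment]:
    """Fragment the parent at the given bonds.

    ``full``: all bonds cut simultaneously, producing k+1 fragments that
    partition the parent. ``single_site``: each event applied independently,
    producing the two flanking fragments per event.
    """
    mode = DigestMode(mode)
    seq, L = record.sequence, len(record.sequence)
    cuts = sorted({ev.position for ev in events})

    def frag(start: int, end: int) -> Fragment:
        return Fragment(parent_id=record.id, start=start, end=end,
                        sequence=seq[start - 1:end],
                        neo_n=start > 1, neo_c=end < L)

    if mode is DigestMode.FULL:
        bounds = [0] + cuts + [L]
        return [frag(bounds[i] + 1, bounds[i + 1])
                for i in range(len(bounds) - 1)]
    out = []
    for p in cuts:
        out.extend([frag(1, p), frag(p + 1, L)])
    return out


def neo_degron_screen(
    fragments: Sequence[Fragment],
    motifs: MotifSet,
    gravy_window: int = 15,
    psi_models: Optional[dict] = None,
    scan_params: ScanParams = ScanParams(include_met_variants=False),
) -> List[NeoDegronReport]:
    """Screen digestion products for degrons at their newly created termini.

    Only neo termini are treated as new: a fragment keeping the parent's
    N terminus is not N-screened (its N-degron status is the parent's), and
    likewise for the C terminus. Initiator-Met processing does not apply to
    neo-N termini, so fragments are scanned as given. Matches are reported in
    fragment coordinates with their parent-coordinate spans alongside.
    """
    out = []
    for fr in fragments:
        rec = ProteinRecord(id=fr.id, sequence=fr.sequence, origin=Origin.FASTA)
        matches = scan_degrons(rec, motifs, params=scan_params)
        neo_n_matches = tuple(
            m for m in matches if fr.neo_n and m.location_class.value == "N_TERMINAL")
        neo_c_matches = tuple(
            m for m in matches if fr.neo_c and m.location_class.value == "C_TERMINAL")
        parent_positions = {
            m: (fr.start + m.start - 1, fr.start + m.end - 1)
            for m in (*neo_n_matches, *neo_c_matches)}
        psi = None
        if psi_models:
            psi = {}
            for label, model in psi_models.items():
                try:
                    psi[label] = model.predict_record(rec)
                except Exception:   # a missing/short terminus is not fatal
                    psi[label] = None
        out.append(NeoDegronReport(
            fragment=fr,
            neo_n_class=n_end_rule_class(fr.sequence[0]) if fr.neo_n else None,
            neo_n_matches=neo_n_matches, neo_c_matches=neo_c_matches,
            terminal=terminal_gravy(rec, window_w=gravy_window),
            parent_positions=parent_positions, psi=psi))
    return out


def load_site_table(path) -> pd.DataFrame:
    """Read a cleavage-site TSV (protein_id, position, enzyme, physiological,
    source)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("protein_id", "position") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {','.join(missing)}")
    return df
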