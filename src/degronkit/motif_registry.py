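"""Degron motif representation, the restricted pattern dialect, and loaders.

Degrons are short linear motifs. The pattern dialect is a deliberately small
regex subset so that every match is enumerable and a brute-force oracle stays
trivial:

* a literal 1-letter residue, e.g. ``K``;
* a character class ``[KR]`` or negated class ``[^P]``;
* the wildcard ``x`` (any of the 20 canonical residues);
* a bounded repeat ``{n}`` or ``{m,n}`` applied to the preceding token.

No anchors, alternation, lookaround or unbounded repeats. Location semantics
(N-terminal / C-terminal / internal) are carried by the motif's location
class, not by the pattern: the scanner enforces anchoring, so a single motif
row stays valid for both initiator-Met variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from ._aa import CANONICAL_SET


class LocationClass(str, Enum):
    N_TERMINAL = "N_TERMINAL"
    C_TERMINAL = "C_TERMINAL"
    INTERNAL = "INTERNAL"


class PatternError(ValueError):
    """Pattern not in the dialect; message names the offending token."""


@dataclass(frozen=True)
class _Token:
    residues: frozenset      # residues this position may take
    min_repeat: int = 1
    max_repeat: int = 1


def _parse_class(pattern: str, i: int) -> Tuple[frozenset, int]:
    j = pattern.find("]", i)
    if j < 0:
        raise PatternError(f"unclosed character class at offset {i} in {pattern!r}")
    body = pattern[i + 1:j]
    negate = body.startswith("^")
    if negate:
        body = body[1:]
    if not body:
        raise PatternError(f"empty character class at offset {i} in {pattern!r}")
    bad = sorted(set(body) - CANONICAL_SET)
    if bad:
        raise PatternError(
            f"non-canonical letter(s) {','.join(bad)} in class at offset {i} "
            f"of {pattern!r}")
    members = frozenset(body)
    if negate:
        members = frozenset(CANONICAL_SET) - members
    return members, j + 1


def _parse_repeat(pattern: str, i: int) -> Tuple[int, int, int]:
    j = pattern.find("}", i)
    if j < 0:
        raise PatternError(f"unclosed repeat at offset {i} in {pattern!r}")
    body = pattern[i + 1:j]
    parts = body.split(",")
    try:
        if len(parts) == 1:
            m = n = int(parts[0])
        elif len(parts) == 2:
            m, n = int(parts[0]), int(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise PatternError(f"malformed repeat {{{body}}} in {pattern!r}") from None
    if m < 0 or n < m or n == 0:
        raise PatternError(f"invalid repeat bounds {{{body}}} in {pattern!r}")
    return m, n, j + 1


class CompiledMotif:
    """A compiled dialect pattern reporting all 1-based inclusive matches."""

    def __init__(self, pattern: str):
        if not pattern:
            raise PatternError("empty pattern")
        tokens: List[_Token] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                residues, i = _parse_class(pattern, i)
                tokens.append(_Token(residues))
            elif ch == "x":
                tokens.append(_Token(frozenset(CANONICAL_SET)))
                i += 1
            elif ch in CANONICAL_SET:
                tokens.append(_Token(frozenset(ch)))
                i += 1
            elif ch == "{":
                if not tokens:
                    raise PatternError(f"repeat with no preceding token in {pattern!r}")
                if tokens[-1].min_repeat != 1 or tokens[-1].max_repeat != 1:
                    raise PatternError(f"double repeat in {pattern!r}")
                m, n, i = _parse_repeat(pattern, i)
                tokens[-1] = _Token(tokens[-1].residues, m, n)
            else:
                raise PatternError(
                    f"token {ch!r} at offset {i} of {pattern!r} is not in the "
                    f"dialect (literal residue, [..], [^..], x, {{m,n}})")
        self.pattern = pattern
        self._tokens = tokens
        self.min_length = sum(t.min_repeat for t in tokens)
        self.max_length = sum(t.max_repeat for t in tokens)

    def _ends_from(self, seq: str, pos: int) -> List[int]:
        """All 0-based end offsets (exclusive) of matches starting at pos."""
        ends = [pos]
        for tok in self._tokens:
            nxt = set()
            for e in ends:
                # consume the mandatory repeats, then optional ones
                k, ok = 0, True
                while k < tok.min_repeat:
                    if e >= len(seq) or seq[e] not in tok.residues:
                        ok = False
                        break
                    e += 1
                    k += 1
                if not ok:
                    continue
                nxt.add(e)
                while k < tok.max_repeat and e < len(seq) and seq[e] in tok.residues:
                    e += 1
                    k += 1
                    nxt.add(e)
            if not nxt:
                return []
            ends = sorted(nxt)
        return ends

    def find_all(self, seq: str) -> List[Tuple[int, int]]:
        """All (start, end) matches, 1-based inclusive, overlaps included."""
        hits = []
        for pos in range(len(seq)):
            for e in self._ends_from(seq, pos):
                hits.append((pos + 1, e))
        return hits

    def matches_at_start(self, seq: str) -> List[Tuple[int, int]]:
        return [(1, e) for e in self._ends_from(seq, 0)]

    def matches_at_end(self, seq: str) -> List[Tuple[int, int]]:
        L = len(seq)
        return [(s, e) for s, e in self.find_all(seq) if e == L]

    def fullmatch(self, seq: str) -> bool:
        return len(seq) in self._ends_from(seq, 0)


@dataclass(frozen=True)
class DegronMotif:
    motif_id: str
    name: str
    pattern: str
    location_class: LocationClass
    pathway: str = ""
    source: str = ""
    compiled: Optional[CompiledMotif] = field(default=None, compare=False, repr=False)

    def matcher(self) -> CompiledMotif:
        return self.compiled if self.compiled is not None else CompiledMotif(self.pattern)


@dataclass(frozen=True)
class MotifSet:
    motifs: tuple
    provenance: str = ""

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)

    def by_id(self, motif_id: str) -> DegronMotif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


class MotifTableError(ValueError):
    pass


_COLUMNS = ["motif_id", "name", "pattern", "location_class", "pathway", "source"]


def _build_motifs(rows: Iterable[dict], provenance: str) -> MotifSet:
    motifs, seen = [], set()
    for i, row in enumerate(rows, start=1):
        missing = [c for c in _COLUMNS[:4] if not str(row.get(c, "") or "").strip()]
        if missing:
            raise MotifTableError(f"row {i}: missing field(s) {','.join(missing)}")
        mid = str(row["motif_id"]).strip()
        if mid in seen:
            raise MotifTableError(f"row {i}: duplicate motif_id {mid!r}")
        seen.add(mid)
        loc_raw = str(row["location_class"]).strip()
        try:
            loc = LocationClass(loc_raw.upper())
        except ValueError:
            raise MotifTableError(
                f"row {i} (motif {mid!r}): unknown location_class {loc_raw!r}"
            ) from None
        pattern = str(row["pattern"]).strip()
        try:
            compiled = CompiledMotif(pattern)
        except PatternError as exc:
            raise MotifTableError(f"row {i} (motif {mid!r}): {exc}") from None
        motifs.append(DegronMotif(
            motif_id=mid, name=str(row["name"]).strip(), pattern=pattern,
            location_class=loc, pathway=str(row.get("pathway", "") or ""),
            source=str(row.get("source", "") or ""), compiled=compiled))
    return MotifSet(motifs=tuple(motifs), provenance=provenance)


def load_motifs(path, format: Optional[str] = None) -> MotifSet:
    """Load a motif table (TSV with header, or a JSON array of objects)."""
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _COLUMNS[:4] if c not in df.columns]
        if missing:
            raise MotifTableError(f"{path}: missing column(s) {','.join(missing)}")
        rows = df.to_dict("records")
    elif format == "json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise MotifTableError(f"{path}: JSON motif file must be an array")
    else:
        raise ValueError(f"unknown motif table format {format!r}")
    return _build_motifs(rows, provenance=path)


def save_motifs(motif_set: MotifSet, path, format: Optional[str] = None) -> None:
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "tsv"
    rows = [{c: (getattr(m, c).value if c == "location_class" else getattr(m, c))
             for c in _COLUMNS} for m in motif_set]
    if format == "tsv":
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown motif table format {format!r}")


def builtin_motifs() -> MotifSet:
    """The packaged starter motif set (documented in the bundled TSV).

    Covers the Arg/N-pathway N-terminal residue classes, representative
    C-degron motifs and representative internal motifs; users extend or
    replace it with their own table via :func:`load_motifs`.
    """
    ref = resources.files("degronkit.data").joinpath("builtin_motifs.tsv")
    with resources.as_file(ref) as p:
        ms = load_motifs(p, format="tsv")
    return MotifSet(motifs=ms.motifs, provenance="degronkit builtin v1")
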