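"""Degron conservation over a user-supplied multiple sequence alignment.

A degron match is mapped from query coordinates into alignment columns, and
four conservation scores (all in [0, 1], versioned as ``SCORE_SCHEME``) are
computed over the non-query rows:

``s1_presence``
    fraction of rows in which the motif matches exactly at the aligned motif
    columns (gapless, spanning them fully) — strict positional preservation.
``s2_window_presence``
    fraction of rows in which the motif matches anywhere within the motif
    columns widened by ``flank`` columns on each side — positional drift
    tolerated. Always >= s1 by construction.
``s3_column_identity``
    mean, over motif columns, of the fraction of rows whose residue equals
    the query residue (a gap counts as a mismatch).
``s4_column_conservation``
    mean, over motif columns, of 1 − Shannon entropy of the column
    (gaps excluded) normalized by log(20).

Rows that are entirely gapped across the motif columns are excluded from all
denominators; a query-only alignment yields no scores (None), not zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

from Bio import AlignIO

from .degron_scanner import DegronMatch
from .motif_registry import DegronMotif
from .seqio import ProteinRecord

SCORE_SCHEME = "degronkit-conservation-v1"
DEFAULT_CONSERVATION_FLANK = 5

_GAPS = {"-", "."}


@dataclass(frozen=True)
class MSA:
    rows: tuple                   # tuple of (id, aligned sequence)
    query_row_id: str
    col_map: tuple                # query position p -> alignment column (1-based)

    @property
    def query_row(self) -> str:
        return dict(self.rows)[self.query_row_id]


@dataclass(frozen=True)
class ConservationScores:
    match_id: str
    s1_presence: Optional[float]
    s2_window_presence: Optional[float]
    s3_column_identity: Optional[float]
    s4_column_conservation: Optional[float]
    n_rows_used: int
    scheme: str = SCORE_SCHEME


class MSAError(ValueError):
    pass


def _sniff_format(path: str) -> str:
    with open(path) as fh:
        head = fh.readline()
    if head.startswith(">"):
        return "fasta"
    if head.startswith("CLUSTAL"):
        return "clustal"
    if head.startswith("# STOCKHOLM"):
        return "stockholm"
    raise MSAError(f"cannot determine alignment format of {path}")


def map_to_msa(record: ProteinRecord, msa_file, query_row_id: str,
               format: Optional[str] = None) -> MSA:
    """Read an alignment and map query positions to alignment columns.

    The ungapped query row must reproduce the query sequence exactly; a
    mismatch is reported with the first differing position.
    """
    path = str(msa_file)
    aln = AlignIO.read(path, format or _sniff_format(path))
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    ids = [r[0] for r in rows]
    if query_row_id not in ids:
        raise MSAError(f"query row {query_row_id!r} absent from alignment "
                       f"(rows: {', '.join(ids[:10])}...)")
    aligned = dict(rows)[query_row_id]
    col_map, ungapped = [], []
    for col, ch in enumerate(aligned, start=1):
        if ch not in _GAPS:
            col_map.append(col)
            ungapped.append(ch)
    ungapped = "".join(ungapped)
    if ungapped != record.sequence:
        diff = next((i for i, (a, b) in enumerate(
            zip(ungapped, record.sequence)) if a != b),
            min(len(ungapped), len(record.sequence)))
        raise MSAError(
            f"sequence_mismatch: ungapped query row differs from record at "
            f"position {diff + 1} "
            f"(row has {ungapped[diff:diff + 1] or 'nothing'!r}, record has "
            f"{record.sequence[diff:diff + 1] or 'nothing'!r})")
    return MSA(rows=rows, query_row_id=query_row_id, col_map=tuple(col_map))


def score_conservation(match: DegronMatch, msa: MSA, motif: DegronMotif,
                       flank: int = DEFAULT_CONSERVATION_FLANK) -> ConservationScores:
    """Compute the four conservation scores for one degron match."""
    try:
        cols = [msa.col_map[p - 1] for p in range(match.start, match.end + 1)]
    except IndexError:
        raise MSAError(f"match {match.start}-{match.end} does not map fully "
                       f"into the alignment") from None
    matcher = motif.matcher()
    n_cols = len(dict(msa.rows)[msa.query_row_id])
    lo = max(1, cols[0] - flank)
    hi = min(n_cols, cols[-1] + flank)
    query_res = list(match.matched_seq)

    others = [(rid, seq) for rid, seq in msa.rows if rid != msa.query_row_id]
    usable = [(rid, seq) for rid, seq in others
              if any(seq[c - 1] not in _GAPS for c in cols)]
    match_id = f"{match.motif_id}@{match.start}-{match.end}"
    if not usable:
        return ConservationScores(match_id, None, None, None, None, 0)

    s1_hits = s2_hits = 0
    for _, seq in usable:
        site = [seq[c - 1] for c in cols]
        if all(ch not in _GAPS for ch in site) and matcher.fullmatch("".join(site)):
            s1_hits += 1
        window = "".join(ch for ch in seq[lo - 1:hi] if ch not in _GAPS)
        if matcher.find_all(window):
            s2_hits += 1

    ident_cols, cons_cols = [], []
    for c, q_aa in zip(cols, query_res):
        column = [seq[c - 1] for _, seq in usable]
        ident_cols.append(sum(ch == q_aa for ch in column) / len(usable))
        residues = [ch for ch in column if ch not in _GAPS]
        if residues:
            counts: Dict[str, int] = {}
            for ch in residues:
                counts[ch] = counts.get(ch, 0) + 1
            # iterate counts in residue order so the float sum is invariant
            # to MSA row order
            entropy = -sum((k / len(residues)) * math.log(k / len(residues))
                           for _, k in sorted(counts.items()))
            cons_cols.append(1.0 - entropy / math.log(20))
        else:
            cons_cols.append(0.0)

    n = len(usable)
    return ConservationScores(
        match_id=match_id,
        s1_presence=s1_hits / n,
        s2_window_presence=s2_hits / n,
        s3_column_identity=sum(ident_cols) / len(ident_cols),
        s4_column_conservation=sum(cons_cols) / len(cons_cols),
        n_rows_used=n)
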