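"""Tripartite degron assembly around each primary motif hit.

Under the tripartite degron model, productive degradation needs (i) the
primary degron motif recognized by an E3 ligase, (ii) secondary degrons —
nearby residues that can accept ubiquitin: lysine, and also cysteine, serine
and threonine — and (iii) a tertiary degron, a flexible disordered region
that can seed unfolding at the proteasome. This module collects, for every
primary match, the candidate ubiquitination sites in the flanking window
(with their structural context) and assigns each one its nearest IDR, then
decorates the report with user-supplied PTM and missense-mutation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .degron_scanner import DegronMatch
from .seqio import ProteinRecord
from .structure_disorder import IDR, ResidueContext

DEFAULT_FLANK = 15
DEFAULT_SITE_WINDOW = 5           # half-window for mean disorder around a site

UBIQUITINATABLE = frozenset("KCST")


@dataclass(frozen=True)
class PTMRecord:
    protein_id: str
    position: int
    ptm_type: str
    source: str = ""


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    position: int
    ref: str
    alt: str
    source: str = ""


@dataclass(frozen=True)
class SecondaryDegron:
    position: int
    residue: str
    rsa: Optional[float]
    ss: str
    in_idr: bool
    mean_flank_disorder: float
    within_primary: bool
    ptms: tuple = ()
    mutations: tuple = ()


@dataclass(frozen=True)
class TertiaryAssignment:
    secondary_position: int
    idr: Optional[IDR]
    distance: Optional[int]       # 0 if inside; None when no IDRs exist


@dataclass(frozen=True)
class PrimaryContext:
    residues: tuple               # ResidueContext slice over the motif
    mean_rsa: Optional[float]
    mean_disorder: float
    fraction_in_idr: float
    ptms: tuple = ()
    mutations: tuple = ()


@dataclass(frozen=True)
class TripartiteReport:
    primary: DegronMatch
    primary_context: PrimaryContext
    secondaries: tuple
    tertiaries: tuple


def idr_distance(position: int, idr: IDR) -> int:
    """Residue distance between a position and an IDR interval (0 inside)."""
    if idr.start <= position <= idr.end:
        return 0
    return min(abs(position - idr.start), abs(position - idr.end))


def find_secondary_degrons(
    match: DegronMatch,
    record: ProteinRecord,
    context: Sequence[ResidueContext],
    idrs: Sequence[IDR] = (),
    flank: int = DEFAULT_FLANK,
    site_window: int = DEFAULT_SITE_WINDOW,
) -> List[SecondaryDegron]:
    """All K/C/S/T sites within the primary match +/- ``flank`` residues.

    Sites inside the motif itself are included with ``within_primary=True``.
    ``mean_flank_disorder`` averages the disorder score over ``site_window``
    residues on each side of the site (clipped to the chain).
    """
    L = len(record.sequence)
    if len(context) != L:
        raise ValueError("context does not cover the protein")
    lo = max(1, match.start - flank)
    hi = min(L, match.end + flank)
    out = []
    for pos in range(lo, hi + 1):
        aa = record.sequence[pos - 1]
        if aa not in UBIQUITINATABLE:
            continue
        ctx = context[pos - 1]
        w_lo, w_hi = max(1, pos - site_window), min(L, pos + site_window)
        window = [context[i - 1].disorder_score for i in range(w_lo, w_hi + 1)]
        out.append(SecondaryDegron(
            position=pos, residue=aa, rsa=ctx.rsa, ss=ctx.ss,
            in_idr=any(idr_distance(pos, idr) == 0 for idr in idrs),
            mean_flank_disorder=sum(window) / len(window),
            within_primary=match.start <= pos <= match.end))
    return out


def assign_tertiary(secondary: SecondaryDegron,
                    idrs: Sequence[IDR]) -> TertiaryAssignment:
    """Nearest IDR to a secondary site; ties go to the N-terminal IDR."""
    if not idrs:
        return TertiaryAssignment(secondary.position, idr=None, distance=None)
    best = min(idrs, key=lambda idr: (idr_distance(secondary.position, idr),
                                      idr.start))
    return TertiaryAssignment(secondary.position, idr=best,
                              distance=idr_distance(secondary.position, best))


def build_tripartite_report(
    match: DegronMatch,
    record: ProteinRecord,
    context: Sequence[ResidueContext],
    idrs: Sequence[IDR] = (),
    flank: int = DEFAULT_FLANK,
    site_window: int = DEFAULT_SITE_WINDOW,
) -> TripartiteReport:
    motif_slice = tuple(context[match.start - 1:match.end])
    rsas = [c.rsa for c in motif_slice if c.rsa is not None]
    secondaries = tuple(find_secondary_degrons(
        match, record, context, idrs=idrs, flank=flank, site_window=site_window))
    primary_ctx = PrimaryContext(
        residues=motif_slice,
        mean_rsa=(sum(rsas) / len(rsas)) if rsas else None,
        mean_disorder=sum(c.disorder_score for c in motif_slice) / len(motif_slice),
        fraction_in_idr=sum(
            any(idr_distance(c.position, idr) == 0 for idr in idrs)
            for c in motif_slice) / len(motif_slice),
    )
    tertiaries = tuple(assign_tertiary(s, idrs) for s in secondaries)
    return TripartiteReport(primary=match, primary_context=primary_ctx,
                            secondaries=secondaries, tertiaries=tertiaries)


def overlay_annotations(
    report: TripartiteReport,
    ptms: Iterable[PTMRecord] = (),
    mutations: Iterable[MutationRecord] = (),
    flank: int = DEFAULT_FLANK,
) -> TripartiteReport:
    """Attach PTMs and missense mutations to a report (pure decoration).

    PTMs attach anywhere within motif +/- flank. Mutations attach within the
    motif itself, and additionally at flank positions that carry a PTM (a
    mutation of a modifiable flank residue can rewire degron availability).
    """
    m = report.primary
    lo, hi = m.start - flank, m.end + flank
    ptms_in = [p for p in ptms if lo <= p.position <= hi]
    ptm_positions = {p.position for p in ptms_in}
    muts_in = [mu for mu in mutations
               if m.start <= mu.position <= m.end or mu.position in ptm_positions]

    primary_ctx = replace(
        report.primary_context,
        ptms=tuple(p for p in ptms_in if m.start <= p.position <= m.end),
        mutations=tuple(mu for mu in muts_in if m.start <= mu.position <= m.end))
    secondaries = tuple(
        replace(s,
                ptms=tuple(p for p in ptms_in if p.position == s.position),
                mutations=tuple(mu for mu in muts_in if mu.position == s.position))
        for s in report.secondaries)
    return replace(report, primary_context=primary_ctx, secondaries=secondaries)


# ---------------------------------------------------------------------------
# annotation table loaders (TSV, documented schemas)

class AnnotationTableError(ValueError):
    pass


def _read_tsv(path, required):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationTableError(f"{path}: missing column(s) {','.join(missing)}")
    return df


def load_ptms(path, protein_length: Optional[int] = None) -> List[PTMRecord]:
    """Load ptms.tsv (protein_id, position, ptm_type, source).

    Rows with out-of-range or non-integer positions are rejected with their
    line number (a warning, not an error).
    """
    import warnings
    df = _read_tsv(path, ["protein_id", "position", "ptm_type"])
    out = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
            if pos < 1 or (protein_length is not None and pos > protein_length):
                raise ValueError
        except ValueError:
            warnings.warn(f"{path} line {i + 2}: bad position "
                          f"{row['position']!r}; row rejected", stacklevel=2)
            continue
        out.append(PTMRecord(row["protein_id"], pos, row["ptm_type"],
                             row.get("source", "")))
    return out


def load_mutations(path, protein_length: Optional[int] = None) -> List[MutationRecord]:
    """Load mutations.tsv (protein_id, position, ref, alt, source)."""
    import warnings
    df = _read_tsv(path, ["protein_id", "position", "ref", "alt"])
    out = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
            if pos < 1 or (protein_length is not None and pos > protein_length):
                raise ValueError
        except ValueError:
            warnings.warn(f"{path} line {i + 2}: bad position "
                          f"{row['position']!r}; row rejected", stacklevel=2)
            continue
        out.append(MutationRecord(row["protein_id"], pos, row["ref"],
                                  row["alt"], row.get("source", "")))
    return out


def load_e3_interactors(path) -> pd.DataFrame:
    """Load e3_interactors.tsv (protein_id, e3_id, source); listed verbatim."""
    return _read_tsv(path, ["protein_id", "e3_id"])


def report_to_rows(report: TripartiteReport, protein_id: str) -> List[dict]:
    """Flatten a report to one row per secondary degron (TSV-friendly)."""
    rows = []
    tert = {t.secondary_position: t for t in report.tertiaries}
    m = report.primary
    base = dict(protein_id=protein_id, motif_id=m.motif_id,
                primary_start=m.start, primary_end=m.end,
                primary_mean_disorder=round(report.primary_context.mean_disorder, 4),
                primary_mean_rsa=report.primary_context.mean_rsa,
                primary_fraction_in_idr=round(report.primary_context.fraction_in_idr, 4))
    if not report.secondaries:
        rows.append({**base, "secondary_position": None})
        return rows
    for s in report.secondaries:
        t = tert[s.position]
        rows.append({
            **base,
            "secondary_position": s.position, "secondary_residue": s.residue,
            "secondary_rsa": s.rsa, "secondary_ss": s.ss,
            "secondary_in_idr": s.in_idr,
            "secondary_mean_flank_disorder": round(s.mean_flank_disorder, 4),
            "within_primary": s.within_primary,
            "tertiary_idr_start": t.idr.start if t.idr else None,
            "tertiary_idr_end": t.idr.end if t.idr else None,
            "tertiary_distance": t.distance,
            "n_ptms": len(s.ptms), "n_mutations": len(s.mutations),
        })
    return rows
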