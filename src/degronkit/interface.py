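"""Pipeline orchestration, report bundling and export.

Runs the full degron workflow for one query protein: motif scan over both
Met variants, terminal analyses (Gravy, N-end-rule class, optional PSI),
conservation (when an MSA is given), disorder/IDR calling (structure pLDDT
mode for PDB queries, sequence mode otherwise), tripartite assembly per
primary match, optional proteolysis + neo-degron screening, and annotation
overlay. Output granularity follows the query type: sequence-only queries
carry no ss/RSA columns. Stages are isolated — a failing optional stage is
reported and the rest of the run continues — and the whole run is
deterministic for fixed inputs, config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import __version__
from .conservation import DEFAULT_CONSERVATION_FLANK, map_to_msa, score_conservation
from .degron_scanner import DEFAULT_GRAVY_WINDOW, scan_degrons, terminal_gravy
from .motif_registry import MotifSet, builtin_motifs, load_motifs
from .proteolysis import (DigestMode, digest, find_cleavage_sites, load_site_table,
                          neo_degron_screen)
from .psi_stability import TerminusKind, load_model
from .seqio import (MAX_QUERY_LENGTH, Origin, ProteinRecord, StructureModel,
                    ValidationLimits, read_fasta, read_structure, validate_query)
from .structure_disorder import (DEFAULT_MIN_IDR_LENGTH, DEFAULT_PLDDT_THRESHOLD,
                                 DEFAULT_SEQUENCE_THRESHOLD, DisorderMode,
                                 disorder_profile, residue_contexts,
                                 secondary_structure, segment_idrs)
from .tripartite import (DEFAULT_FLANK, DEFAULT_SITE_WINDOW, build_tripartite_report,
                         load_mutations, load_ptms, overlay_annotations,
                         report_to_rows)

logger = logging.getLogger(__name__)

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


@dataclass
class RunConfig:
    """Tunable parameters of a run; defaults mirror the documented server
    defaults where those are printed (pLDDT < 70, sequence disorder > 0.5,
    Gravy window 15, query limit 40000)."""

    motif_table: Optional[str] = None          # None -> packaged starter set
    disorder_mode: Optional[str] = None        # None -> by query type
    disorder_threshold: Optional[float] = None
    idr_min_len: int = DEFAULT_MIN_IDR_LENGTH
    tripartite_flank: int = DEFAULT_FLANK
    tripartite_site_window: int = DEFAULT_SITE_WINDOW
    conservation_flank: int = DEFAULT_CONSERVATION_FLANK
    gravy_window: int = DEFAULT_GRAVY_WINDOW
    max_query_length: int = MAX_QUERY_LENGTH
    psi_models: dict = field(default_factory=dict)   # terminus label -> path
    seed: int = 0
    online: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


@dataclass
class PipelineInputs:
    fasta: Optional[str] = None
    pdb: Optional[str] = None
    accession: Optional[str] = None
    msa: Optional[str] = None
    msa_query_row: Optional[str] = None
    ptms: Optional[str] = None
    mutations: Optional[str] = None
    cleave_enzyme: Optional[str] = None
    cleave_sites: Optional[List[int]] = None
    cleave_motif: Optional[str] = None
    cleave_table: Optional[str] = None


@dataclass
class ReportBundle:
    sections: dict                 # name -> DataFrame
    metadata: dict

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.sections[name]


SECTION_ORDER = ["matches", "tripartite", "fragments", "conservation", "psi",
                 "annotations", "metadata"]


def fetch_uniprot(accession: str, timeout: float = 30.0) -> ProteinRecord:
    """Fetch the canonical sequence for a UniProt accession (network)."""
    url = UNIPROT_FASTA_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"unexpected UniProt response for {accession}")
    seq = "".join(lines[1:]).upper()
    return ProteinRecord(id=accession, sequence=seq,
                         description=lines[0][1:], origin=Origin.ACCESSION)


def _resolve_query(inputs: PipelineInputs, config: RunConfig):
    given = [x is not None for x in (inputs.fasta, inputs.pdb, inputs.accession)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of fasta, pdb, accession")
    model = None
    if inputs.fasta:
        record = read_fasta(inputs.fasta)[0]
    elif inputs.pdb:
        model = read_structure(inputs.pdb)
        record = model.record
    else:
        if not config.online:
            raise ValueError("accession queries need online=True "
                             "(network access is off by default)")
        record = fetch_uniprot(inputs.accession)
    limits = ValidationLimits(max_length=config.max_query_length)
    result = validate_query(model if model is not None else record, limits)
    if not result.ok:
        raise ValueError("invalid query: " + "; ".join(
            f"{c.value}: {m}" for c, m in result.failures))
    return record, model


def run_pipeline(inputs: PipelineInputs,
                 config: RunConfig = RunConfig(),
                 motifs: Optional[MotifSet] = None) -> ReportBundle:
    """Execute the full workflow for one query; returns a ReportBundle."""
    record, model = _resolve_query(inputs, config)
    if motifs is None:
        motifs = (load_motifs(config.motif_table) if config.motif_table
                  else builtin_motifs())
    errors = {}

    # 1. degron scan (both Met variants)
    matches = scan_degrons(record, motifs)
    matches_df = pd.DataFrame([{
        "protein_id": record.id, "motif_id": m.motif_id, "start": m.start,
        "end": m.end, "matched_seq": m.matched_seq,
        "location_class": m.location_class.value,
        "met_variant": m.met_variant.value, "terminus": m.terminus.value,
    } for m in matches])

    # 2. terminal analyses
    term = terminal_gravy(record, window_w=config.gravy_window)
    terminal_meta = {
        "n_gravy": term.n_gravy, "c_gravy": term.c_gravy,
        "gravy_window": term.window_w,
        "n_end_class": {k.value: v.value for k, v in term.n_end_class.items()},
    }

    # 3. PSI predictions (if trained models configured)
    psi_rows = []
    for label, model_path in (config.psi_models or {}).items():
        try:
            psi_model = load_model(model_path)
            pred = psi_model.predict_record(record)
            psi_rows.append({"protein_id": record.id, "terminus": label,
                             "psi": pred.psi, "category": pred.category.value})
        except Exception as exc:
            errors[f"psi:{label}"] = str(exc)
            logger.warning("PSI stage (%s) failed: %s", label, exc)
    psi_df = pd.DataFrame(psi_rows, columns=["protein_id", "terminus", "psi",
                                             "category"])

    # 4. disorder / structural context
    if config.disorder_mode is not None:
        mode = DisorderMode(config.disorder_mode)
    else:
        mode = (DisorderMode.STRUCTURE_PLDDT if model is not None
                else DisorderMode.SEQUENCE)
    profile = disorder_profile(model if mode is DisorderMode.STRUCTURE_PLDDT
                               else record, mode=mode,
                               threshold=config.disorder_threshold)
    ss_asa = secondary_structure(model) if model is not None else None
    context = residue_contexts(model if model is not None else record,
                               profile, ss_asa)
    idrs = segment_idrs(profile, min_len=config.idr_min_len)

    # 5. conservation (optional)
    cons_rows = []
    if inputs.msa:
        try:
            msa = map_to_msa(record, inputs.msa,
                             inputs.msa_query_row or record.id)
            for m in matches:
                if m.met_variant.value != "as_given":
                    continue
                sc = score_conservation(m, msa, motifs.by_id(m.motif_id),
                                        flank=config.conservation_flank)
                cons_rows.append({
                    "protein_id": record.id, "motif_id": m.motif_id,
                    "start": m.start, "end": m.end, "s1_presence": sc.s1_presence,
                    "s2_window_presence": sc.s2_window_presence,
                    "s3_column_identity": sc.s3_column_identity,
                    "s4_column_conservation": sc.s4_column_conservation,
                    "n_rows_used": sc.n_rows_used})
        except Exception as exc:
            errors["conservation"] = str(exc)
            logger.warning("conservation stage failed: %s", exc)
    cons_df = pd.DataFrame(cons_rows, columns=[
        "protein_id", "motif_id", "start", "end", "s1_presence",
        "s2_window_presence", "s3_column_identity", "s4_column_conservation",
        "n_rows_used"])

    # 6. tripartite assembly (+ annotation overlay)
    ptms = load_ptms(inputs.ptms, len(record.sequence)) if inputs.ptms else []
    muts = (load_mutations(inputs.mutations, len(record.sequence))
            if inputs.mutations else [])
    ptms = [p for p in ptms if p.protein_id == record.id]
    muts = [m for m in muts if m.protein_id == record.id]
    tri_rows = []
    for m in matches:
        report = build_tripartite_report(
            m, record, context, idrs=idrs, flank=config.tripartite_flank,
            site_window=config.tripartite_site_window)
        report = overlay_annotations(report, ptms, muts,
                                     flank=config.tripartite_flank)
        tri_rows.extend(report_to_rows(report, record.id))
    tri_columns = ["protein_id", "motif_id", "primary_start", "primary_end",
                   "primary_mean_disorder", "primary_mean_rsa",
                   "primary_fraction_in_idr", "secondary_position",
                   "secondary_residue", "secondary_rsa", "secondary_ss",
                   "secondary_in_idr", "secondary_mean_flank_disorder",
                   "within_primary", "tertiary_idr_start", "tertiary_idr_end",
                   "tertiary_distance", "n_ptms", "n_mutations"]
    tri_df = pd.DataFrame(tri_rows, columns=tri_columns)
    if model is None:
        # sequence-only query: no structural columns in the output
        tri_df = tri_df.drop(columns=[c for c in ("primary_mean_rsa",
                                                  "secondary_rsa",
                                                  "secondary_ss")
                                      if c in tri_df.columns])

    # 7. proteolysis + neo-degron screen (optional)
    frag_rows = []
    cleave_requested = any([inputs.cleave_enzyme, inputs.cleave_sites,
                            inputs.cleave_motif, inputs.cleave_table])
    if cleave_requested:
        try:
            events = find_cleavage_sites(
                record,
                rule=inputs.cleave_enzyme,
                positions=inputs.cleave_sites,
                motif=inputs.cleave_motif,
                site_rows=(load_site_table(inputs.cleave_table)
                           if inputs.cleave_table else None))
            fragments = digest(record, events, mode=DigestMode.FULL)
            for rep in neo_degron_screen(fragments, motifs,
                                         gravy_window=config.gravy_window):
                fr = rep.fragment
                frag_rows.append({
                    "protein_id": record.id, "fragment_id": fr.id,
                    "start": fr.start, "end": fr.end, "length": len(fr.sequence),
                    "neo_n": fr.neo_n, "neo_c": fr.neo_c,
                    "neo_n_residue": fr.sequence[0] if fr.neo_n else None,
                    "neo_n_class": rep.neo_n_class.value if rep.neo_n_class else None,
                    "neo_n_motifs": ";".join(m.motif_id for m in rep.neo_n_matches),
                    "neo_c_motifs": ";".join(m.motif_id for m in rep.neo_c_matches),
                    "n_gravy": rep.terminal.n_gravy,
                    "c_gravy": rep.terminal.c_gravy})
        except Exception as exc:
            errors["proteolysis"] = str(exc)
            logger.warning("proteolysis stage failed: %s", exc)
    frag_df = pd.DataFrame(frag_rows, columns=[
        "protein_id", "fragment_id", "start", "end", "length", "neo_n",
        "neo_c", "neo_n_residue", "neo_n_class", "neo_n_motifs",
        "neo_c_motifs", "n_gravy", "c_gravy"])

    ann_rows = ([{"protein_id": p.protein_id, "position": p.position,
                  "kind": "ptm", "detail": p.ptm_type, "source": p.source}
                 for p in ptms] +
                [{"protein_id": m.protein_id, "position": m.position,
                  "kind": "mutation", "detail": f"{m.ref}>{m.alt}",
                  "source": m.source} for m in muts])
    ann_df = pd.DataFrame(ann_rows, columns=["protein_id", "position", "kind",
                                             "detail", "source"])

    metadata = {
        "degronkit_version": __version__,
        "protein_id": record.id, "length": len(record.sequence),
        "origin": record.origin.value,
        "query_has_structure": model is not None,
        "disorder": {"mode": profile.mode.value, "threshold": profile.threshold,
                     "method": profile.method},
        "n_idrs": len(idrs),
        "idrs": [[i.start, i.end] for i in idrs],
        "terminal": terminal_meta,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "motif_set": {"provenance": motifs.provenance, "n_motifs": len(motifs)},
        "stage_errors": errors,
    }
    sections = {
        "matches": matches_df, "tripartite": tri_df, "fragments": frag_df,
        "conservation": cons_df, "psi": psi_df, "annotations": ann_df,
    }
    return ReportBundle(sections=sections, metadata=metadata)


def export_report(bundle: ReportBundle, out_dir, format: str = "tsv_bundle"):
    """Write a bundle as an xlsx workbook, a TSV bundle + manifest, or JSON.

    Sheet/file names follow SECTION_ORDER; empty sections are written with
    their header only. Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if format == "workbook":
        path = out_dir / "degronkit_report.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as xls:
            for name, df in bundle.sections.items():
                df.to_excel(xls, sheet_name=name, index=False)
            meta = pd.DataFrame([{"key": k, "value": json.dumps(v)}
                                 for k, v in bundle.metadata.items()])
            meta.to_excel(xls, sheet_name="metadata", index=False)
        written.append(path)
    elif format == "tsv_bundle":
        for name, df in bundle.sections.items():
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        manifest = out_dir / "manifest.json"
        with open(manifest, "w") as fh:
            json.dump({"sections": [s for s in bundle.sections],
                       "metadata": bundle.metadata}, fh, indent=1, default=str)
        written.append(manifest)
    elif format == "json":
        path = out_dir / "degronkit_report.json"
        doc = {"metadata": bundle.metadata,
               "sections": {name: df.to_dict("records")
                            for name, df in bundle.sections.items()}}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=str)
        written.append(path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def read_tsv_bundle(out_dir) -> ReportBundle:
    """Re-read a tsv_bundle export (round-trip counterpart of export_report)."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    sections = {}
    for name in manifest["sections"]:
        try:
            sections[name] = pd.read_csv(out_dir / f"{name}.tsv", sep="\t")
        except pd.errors.EmptyDataError:
            sections[name] = pd.DataFrame()
    return ReportBundle(sections=sections, metadata=manifest["metadata"])
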