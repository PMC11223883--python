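# degronkit

Offline toolkit for **degron** discovery and context analysis in proteins.
Degrons are short linear motifs that E3 ubiquitin ligases recognize to target
a protein for proteasomal degradation. Whether a candidate motif actually
drives degradation depends on its context — the *tripartite degron* model
distinguishes the **primary** degron (the recognized motif), **secondary**
degrons (nearby residues that can accept ubiquitin: K, and also C, S, T) and
a **tertiary** degron (a flexible intrinsically disordered region, IDR, that
seeds unfolding at the proteasome). Termini matter especially: the N- and
C-degron pathways are triggered by destabilizing residues or motifs at a
protein's ends, and proteolytic processing constantly creates *neo-termini*
that can expose such degrons.

degronkit is a library + CLI for researchers studying protein turnover. It:

* scans a protein (both initiator-Met variants) for degron motifs with
  N-terminal / C-terminal / internal location semantics, reporting terminal
  hydrophobicity (Gravy over the terminal 15 residues) and the Arg/N-end-rule
  class of the N-terminal residue;
* derives per-residue structural context: relative solvent accessibility
  (RSA = ASA / MaxASA, Sander maxima), disorder from pLDDT-carrying B-factors
  (`disordered ⇔ pLDDT < 70`) or from sequence (`score > 0.5`), and IDR
  segmentation (continuous disordered runs ≥ 10 residues by default);
* assembles the tripartite report per primary match: K/C/S/T secondary sites
  in a ±15-residue flank with RSA/ss/disorder context, the nearest IDR per
  site, and overlay of user-supplied PTM and missense-mutation tables;
* simulates proteolysis — user motif/site, validated site tables, or 35
  built-in protease rules with PeptideCutter-compatible subsite semantics —
  and re-screens the newly created termini for N-/C-degrons;
* scores degron conservation over a user-supplied MSA with four [0,1]
  scores (anchored presence, windowed presence, column identity, column
  conservation);
* trains and applies terminal-peptide stability regressors: PSI (Protein
  Stability Index, from GPS reporter assays; low PSI = unstable terminus) is
  predicted from physicochemical descriptors of the terminal 23-mer computed
  over nested windows (whole peptide and terminal 10/8/6/4/2 residues),
  with five stability categories cut at the training 20/40/60/80th
  percentiles. `PSIRegressor` is a scikit-learn estimator and composes with
  sklearn model selection.

## Worked example: a UBL-fold precursor processed by a DUB

Many ubiquitin-fold precursor proteins (e.g. the splicing factor SDE2) are
matured by deubiquitinating enzymes that cleave immediately after the
diglycine closing the UBL domain, which can expose a destabilizing residue
at the new N terminus. The packaged synthetic precursor
(`degronkit.examples.ubl_precursor_record`) has its diGly at 76–77 and a
lysine at 78:

```bash
python -c "from degronkit.examples import ubl_precursor_record as r; \
           from degronkit.seqio import write_fasta; write_fasta([r()], 'prec.fasta')"
degronkit cleave --fasta prec.fasta --site 77
```

prints

```
protein_id	fragment_id	start	end	neo_n	neo_c	neo_n_class	neo_n_motifs	neo_c_motifs	n_gravy	c_gravy
synthetic_ubl_precursor	synthetic_ubl_precursor:1-77	1	77	False	True			CT_GG	0.607	-0.4
synthetic_ubl_precursor	synthetic_ubl_precursor:78-128	78	128	True	False	type1_primary	NT_R1		-2.527	-2.22
```

Reading: cutting bond 77|78 yields the UBL fragment 1–77 (its *new* C
terminus ends in -GG, flagged as the `CT_GG` C-degron) and the C-domain
fragment 78–128 whose neo-N residue K78 is a type-1 primary destabilizing
residue of the Arg/N-degron pathway (`NT_R1` anchored at the fragment
start) — exactly the configuration that routes such fragments to the
proteasome. The `n_gravy`/`c_gravy` columns give the mean Kyte–Doolittle
hydropathy of each fragment's terminal 15 residues.

The same analysis for the real precursor runs against UniProt with
`degronkit run --accession Q6IQ49 --online --site 77 -o out/` (network
required).

Other entry points: `degronkit scan` (motif scanning), `degronkit enzymes`
(the 35 protease rules), `degronkit psi-train` / `degronkit psi-predict`
(PSI models from a GPS-style TSV: `protein_id  terminus  peptide  psi`),
and `degronkit run` (full workflow; exports an xlsx workbook, a TSV bundle
or JSON with sheets/files `matches`, `tripartite`, `fragments`,
`conservation`, `psi`, `annotations`, `metadata`).

## Motif tables

Motifs are rows of `motif_id, name, pattern, location_class, pathway,
source` (TSV or JSON). Patterns use a small, fully enumerable dialect:
literal residues, `[KR]` / `[^P]` classes, the wildcard `x`, and bounded
repeats `{n}` / `{m,n}` — no anchors (location is carried by
`location_class`: `N_TERMINAL`, `C_TERMINAL`, `INTERNAL`). The packaged
starter set (`src/degronkit/data/builtin_motifs.tsv`, citations inline)
covers the Arg/N N-terminal residue classes, representative C-degrons
(-GG, -RG, -RxxG, -EE, -R, -Vx, -A) and representative internal motifs
(D-box, KEN-box, ABBA); replace or extend it with your own table via
`--motifs` / `load_motifs`.

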