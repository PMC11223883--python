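# Methods

This note documents the models, conventions and numerical choices behind
degronkit, what the synthetic data emulate, and the known limitations.

## Coordinates and Met variants

All positions are 1-based, inclusive, and reported in the frame of the
sequence as given. Because N-terminal methionine excision exposes residue 2
co-translationally, every scan runs on both the as-given and the
Met-cleaved variant (sequences not starting with M, and the degenerate
single-residue "M", have only the as-given form); hits found on the cleaved
variant are mapped back with a +1 offset and flagged `met_cleaved`. A
consequence asserted by the tests: every N-terminal match on the cleaved
variant starts at full-length position 2.

Query limits follow the server-style constraints: sequences must be
canonical 20-letter amino acids (a config switch admits X, which never
satisfies any motif character class) and shorter than 40 000 residues
(exclusive); structures must be single-model, single-chain PDB files with
residues numbered continuously from 1 and under 5 MB. Validation collects
*all* violations rather than failing fast. PDB parsing keeps the default
altloc conformer and ignores HETATM records.

## Motif dialect

Degron motifs in the literature are short linear motifs, so the pattern
language is deliberately restricted to what is enumerable by brute force:
literals, character classes (optionally negated), the wildcard `x` and
bounded repeats. No anchors, alternation, lookaround, or unbounded
repeats. Location semantics live in the motif's location class, enforced by
the scanner (N-terminal motifs anchored at variant position 1, C-terminal
at the last residue), so one motif row serves both Met variants. All
occurrences are reported, including overlapping and nested ones — the
tripartite analysis is per-match and no greedy suppression is applied. The
matcher is property-tested against a positional try-everything oracle.

The packaged starter set is intentionally small and documented; the full
curated collections users may have (downloaded motif tables) load through
the same TSV/JSON schema.

## Disorder, RSA and IDRs

* **Structure mode**: the PDB B-factor column is read verbatim as
  pLDDT/LDDT; a residue is disordered when its score is below the threshold
  (default 70). An all-zero column triggers a warning (likely not a
  predicted model). Note the known caveat that low pLDDT only partially
  overlaps sequence-predicted disorder; the threshold is a config knob.
* **Sequence mode**: a per-residue score in [0,1], disordered above 0.5.
  If an external predictor adapter (e.g. an IUPred-style tool wrapper) is
  configured it is used; otherwise a built-in windowed hydropathy/net-charge
  heuristic runs: over a 21-residue window, the folding index
  `2.785·<H> − |<q>| − 1.151` (Kyte–Doolittle hydropathy rescaled to [0,1],
  mean net charge with His at +0.5) is mapped to a disorder score
  `clip(0.5 − index, 0, 1)`, so the 0.5 decision boundary coincides with a
  zero folding index. This heuristic is a labelled substitute
  (`builtin_hydropathy_charge_heuristic` in outputs), adequate for
  low-complexity charged tails vs hydrophobic cores, not a replacement for a
  dedicated predictor.
* **RSA**: absolute ASA (from a DSSP-style adapter) divided by the Sander
  per-residue maxima, clamped at 1. The constants table ships in
  `degronkit._aa.SANDER_MAX_ASA` (Rost & Sander convention). DSSP itself is
  never re-implemented: without an adapter, secondary structure degrades to
  `'-'` and ASA/RSA to unavailable, with a logged warning; an adapter
  failure likewise degrades rather than aborting the run.
* **IDRs** are maximal runs of disordered residues of length ≥ 10
  (configurable); each carries its mean disorder score.

## Tripartite assembly

For each primary match, all K/C/S/T residues within match ± 15 residues
(config `tripartite_flank`) are secondary-degron candidates; residues
inside the motif itself are included and flagged `within_primary`. Each
site carries RSA, secondary structure, IDR membership and the mean disorder
over ±5 residues around the site (config `tripartite_site_window`; the
window clips at the chain ends). The tertiary assignment per site is the
IDR minimizing interval distance (`0` inside, else
`min(|p−start|, |p−end|)`), ties broken toward the N-terminal IDR; with no
IDRs the assignment is explicitly empty rather than zero.

Annotation overlay is pure decoration: PTMs attach anywhere in motif ∪
flanks; missense mutations attach within the motif and additionally at
flank positions that carry a PTM (mutating a modifiable flank residue can
rewire degron availability). Malformed annotation rows are rejected with
their line numbers as warnings.

## Proteolysis

Cleavage specificity is a set of subsite context patterns over
P4..P1 | P1'..P2' with one marked scissile bond, plus optional exception
patterns that veto a cut. A position token never matches beyond the chain:
a rule demanding context outside the sequence cannot fire at that bond.
This matches how lookaround-based rule engines behave at chain termini and
makes the boundary behaviour explicit and testable. The cut convention is
that an event at position p cleaves bond p|p+1 — so "cleavage at position
77" produces fragments 1–77 and 78–L, and residue 78 becomes the neo-N
terminus.

The built-in registry implements 35 proteolytic enzymes with the published
PeptideCutter (ExPASy) specificities, including the ten caspases, both
pepsins and chymotrypsin variants, and trypsin with its documented
exception subsites. The engine is cross-checked in tests against the
independent ExPASy regex rules shipped by pyteomics (restricted to the
shared 34 enzymes; LysN completes our registry).

Digestion modes: `full` (all bonds cut simultaneously; the fragments
partition the parent — a fuzz-tested conservation property) and
`single_site` (each event independently, yielding the two flanking
fragments). Missed-cleavage enumeration is future work. Only *neo* termini
of fragments are screened as new: the neo-N residue's Arg/N class (type-1
R/K/H; type-2 F/W/Y/L/I; secondary D/E; tertiary N/Q/C; else stabilizing —
user-overridable table), anchored N-/C-terminal motif scans (without Met
processing, which does not apply to internal cleavage products), terminal
Gravy, and optionally PSI of the new terminal 23-mer.

## Conservation scores

The four MSA scores (scheme id `degronkit-conservation-v1`) are this
package's documented definitions spanning strict positional preservation
and positional drift: s1 anchored presence, s2 windowed presence (motif
columns ± 5 by default), s3 mean column identity to the query, s4 mean
column conservation (1 − Shannon entropy / ln 20, gaps excluded). Gaps
never match motif classes; rows entirely gapped over the motif columns are
excluded from all denominators, and a query-only alignment reports
not-available rather than 0. s2 ≥ s1 holds by construction and is
property-tested, as is invariance to row order (the entropy sum iterates
residues in sorted order so even float rounding is order-independent). One
deliberate non-property: adding a query-identical row raises s1–s3 but can
*lower* s4 when orthologs perfectly conserve a different residue —
entropy-based conservation and query-identity measure different things.

## PSI models

Terminal 23-mers are featurized with sequence-derived physicochemical
descriptors — amino-acid composition (20), Gravy, net charge at pH 7,
isoelectric point, molecular weight, aromaticity and aliphatic index, plus
the effective window length — over the whole peptide and the terminal
10/8/6/4/2 residues (162 features). For N termini, the windows exclude the
initiator methionine whether it is present or absent; the full-peptide
block keeps the sequence as given. Charge and pI come from Biopython's
Henderson–Hasselbalch implementation; window descriptors are cached since
short windows repeat heavily across a dataset.

One regressor is trained per terminus kind (N Met-cleaved, N Met-retained,
C) on a 90:10 train:test split, with 5-fold random-permutation
cross-validation (20% validation per fold) reported alongside held-out R²
and RMSE. The backend is sklearn's `HistGradientBoostingRegressor` with
modest defaults (300 iterations, learning rate 0.1) and a fixed seed (42 by
default); hyperparameter search is left to the user via the sklearn API
(the estimator composes with `GridSearchCV` etc.). Stability categories
are cut at the 20/40/60/80th percentiles of the *training* PSI
distribution, right-closed (psi = q80 is `stable`); degenerate cut points
map to `medium` with a warning. Models are persisted via joblib with a
schema tag.

### Synthetic PSI data

The generator emulates GPS-style training tables: random 23-mers drawn
from human-proteome amino-acid frequencies (Met-retained N-peptides start
with M), with PSI = effect(peptide) + Gaussian noise. The default
parameter-recovery condition — PSI linear in full-window Gravy (slope 2),
σ = 0.1, n = 5000 — trains to held-out R² ≥ 0.9 (in practice ≈ 0.99). What
this shows: the featurization exposes the signal and the training protocol
recovers a clean monotone effect. What it does not show: performance on
real GPS data, where PSI reflects degron biology far richer than
hydropathy; the published real-data metrics require the external GPS
tables, which users can supply through `load_gps_table` and the same
training API.

## Pipeline

Stages run scan → terminal analyses → PSI → conservation → disorder/
structure → tripartite → proteolysis → annotations; optional stages that
fail are recorded in `metadata.stage_errors` and do not abort the run.
Output granularity follows the query type: sequence-only queries omit
ss/RSA columns and use sequence-mode disorder; PDB queries use the
B-factor/pLDDT route. Runs are deterministic for fixed inputs, config and
seed, and the exported TSV bundle re-reads to the same tables. Accession
queries fetch from UniProt only behind an explicit `online` flag.

## Problem sizes in checks

The randomized self-checks use sequences ≤ 100 residues, motif sets ≤ 10,
200–500 instances per property, and n = 5000 for PSI recovery — sizes
chosen so the whole verification suite completes in well under a minute on
one CPU while exercising every code path the properties describe.

## Known limitations

* The built-in sequence-disorder heuristic is coarse; use a dedicated
  predictor adapter for serious IDR work.
* Structural (non-linear) degrons are out of scope; only linear motifs are
  matched.
* The packaged motif set is a starter, not a curated census.
* PeptideCutter rules are qualitative specificities; no cleavage-kinetics
  modelling.
* PSI models shipped from synthetic data are demonstrations; train on real
  GPS tables for biological use. No trained weights are bundled.
* mmCIF structures and AlphaFold fragment stitching (>2700 aa models) are
  not supported; supply a merged single-chain PDB.
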