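"""Synthetic example proteins for demos and self-contained tests.

``ubl_precursor_record`` builds a SYNTHETIC ubiquitin-fold precursor: the
human ubiquitin sequence (1-76, a public, universally known 76-mer) behind
an initiator Met, followed by a lysine and a low-complexity acidic/serine
tail. It emulates the architecture of DUB-matured precursors such as SDE2:
a UBL domain closed by a diglycine motif (here at positions 76-77), whose
cleavage after position 77 exposes a destabilizing lysine at position 78 as
the neo-N terminus of the C-fragment. It is NOT the SDE2 sequence; it exists
so the post-proteolytic N-degron workflow can be exercised offline. For the
real case, fetch UniProt Q6IQ49 with ``interface.fetch_uniprot`` (online).
"""

from __future__ import annotations

from .seqio import Origin, ProteinRecord

_UBIQUITIN_1_76 = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

# low-complexity, charge/Ser-rich (disorder-prone) tail for the C-domain,
# carrying one internal KEN-box so downstream stages have a primary motif
_TAIL = "SESEDSPKENSEESSPEKSDSEEPSKESPEDSSEEKSPSESEDKSPESSE"

DIGLYCINE_CUT_POSITION = 77      # bond 77|78: releases the UBL, exposes K78
NEO_N_POSITION = 78


def ubl_precursor_record() -> ProteinRecord:
    """A synthetic DUB-processed UBL precursor (diGly at 76-77, Lys at 78)."""
    seq = "M" + _UBIQUITIN_1_76 + "K" + _TAIL
    assert seq[75:77] == "GG" and seq[77] == "K"
    return ProteinRecord(id="synthetic_ubl_precursor", sequence=seq,
                         description="synthetic UBL-fold precursor "
                                     "(ubiquitin 1-76 + K + acidic tail)",
                         origin=Origin.FASTA)
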