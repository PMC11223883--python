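import random
import re

import pandas as pd
import pytest
from pyteomics import parser as pyt_parser

from conftest import make_motif, make_motif_set, random_sequence
from degronkit.degron_scanner import NEndClass
from degronkit.motif_registry import LocationClass
from degronkit.proteolysis import (CleavageEvent, CleavageSource, DigestMode,
                                   RulePatternError, UnknownEnzymeError,
                                   builtin_rules, digest, find_cleavage_sites,
                                   get_rule, neo_degron_screen)
from degronkit.seqio import ProteinRecord


def trypsin_oracle(seq):
    """Hand-applied trypsin rule: after K/R not before P, plus the WKP/MRP
    positive and CKD/DKD/CKH/CKY/CRK/RRH/RRR negative subsites."""
    cuts = []
    for p in range(1, len(seq)):
        p1, p1p = seq[p - 1], seq[p]
        p2 = seq[p - 2] if p >= 2 else ""
        hit = (p1 in "KR" and p1p != "P") or \
              (p2 == "W" and p1 == "K" and p1p == "P") or \
              (p2 == "M" and p1 == "R" and p1p == "P")
        veto = (p2 in "CD" and p1 == "K" and p1p == "D") or \
               (p2 == "C" and p1 == "K" and p1p in "HY") or \
               (p2 == "C" and p1 == "R" and p1p == "K") or \
               (p2 == "R" and p1 == "R" and p1p in "HR")
        if hit and not veto:
            cuts.append(p)
    return cuts


def pyteomics_cuts(seq, rule_regex, exception_regex=None):
    """Independent oracle: bond positions from the pyteomics ExPASy regexes."""
    cuts = {m.end() for m in re.finditer(rule_regex, seq)}
    if exception_regex:
        cuts -= {m.end() for m in re.finditer(exception_regex, seq)}
    return sorted(p for p in cuts if 1 <= p <= len(seq) - 1)


class TestRegistry:
    def test_exactly_35_enzymes(self):
        rules = builtin_rules()
        assert len(rules) == 35
        assert len({r.enzyme for r in rules}) == 35

    def test_trypsin_rule_shape(self):
        rule = get_rule("Trypsin")
        assert any("[KR]" in s and "[^P]" in s for s in rule.sites)
        assert rule.exceptions    # documented subsite vetoes present

    def test_unknown_enzyme(self):
        with pytest.raises(UnknownEnzymeError, match="unknown_enzyme"):
            get_rule("NoSuchEnzyme")

    def test_lookup_case_insensitive(self):
        assert get_rule("lysc").enzyme == "LysC"


class TestFindSites:
    def test_trypsin_toy_proline_veto(self):
        rec = ProteinRecord(id="p", sequence="AKRPGKA")
        events = find_cleavage_sites(rec, rule="Trypsin")
        assert [e.position for e in events] == [2, 6]
        assert all(e.source is CleavageSource.RULE for e in events)

    @pytest.mark.parametrize("seq", ["AKRPGKA", "WKPMRPA", "CKDRRHA",
                                     "KKKKKK", "ARNDCEQGHILKMFPSTWYV"])
    def test_trypsin_equals_hand_oracle(self, seq):
        rec = ProteinRecord(id="p", sequence=seq)
        got = [e.position for e in find_cleavage_sites(rec, rule="Trypsin")]
        assert got == trypsin_oracle(seq)

    @pytest.mark.parametrize("ours,pyt", [
        ("Trypsin", "trypsin"),
        ("LysC", "lysc"),
        ("Arg-C proteinase", "arg-c"),
        ("Asp-N endopeptidase", "asp-n"),
        ("Glutamyl endopeptidase", "glutamyl endopeptidase"),
        ("Chymotrypsin high specificity", "chymotrypsin high specificity"),
        ("Chymotrypsin low specificity", "chymotrypsin low specificity"),
        ("Thermolysin", "thermolysin"),
        ("Proline-endopeptidase", "proline endopeptidase"),
        ("Pepsin (pH 1.3)", "pepsin ph1.3"),
        ("Pepsin (pH >2)", "pepsin ph2.0"),
        ("Thrombin", "thrombin"),
        ("Factor Xa", "factor xa"),
        ("Caspase 1", "caspase 1"),
        ("Caspase 3", "caspase 3"),
        ("Granzyme B", "granzyme b"),
        ("Staphylococcal peptidase I", "staphylococcal peptidase i"),
        ("Hydroxylamine", "hydroxylamine"),
        ("CNBr", "cnbr"),
        ("Enterokinase", "enterokinase"),
    ])
    def test_rule_engine_agrees_with_pyteomics_regexes(self, ours, pyt, rng):
        """Dual-route check: our subsite engine vs the ExPASy regex rules."""
        regex = pyt_parser.expasy_rules[pyt]
        exc = pyt_parser.expasy_rules["trypsin_exception"] if pyt == "trypsin" \
            else None
        rule = get_rule(ours)
        for _ in range(60):
            seq = random_sequence(rng, 8, 50)
            got = [e.position
                   for e in find_cleavage_sites(
                       ProteinRecord(id="p", sequence=seq), rule=rule)]
            assert got == pyteomics_cuts(seq, regex, exc), (ours, seq)

    def test_user_motif_requires_bond_marker(self):
        rec = ProteinRecord(id="p", sequence="AGGKA")
        with pytest.raises(RulePatternError, match="bond"):
            find_cleavage_sites(rec, motif="GG")
        events = find_cleavage_sites(rec, motif="GG|")
        assert [e.position for e in events] == [3]

    def test_explicit_positions_validated(self):
        rec = ProteinRecord(id="p", sequence="AGGKA")
        events = find_cleavage_sites(rec, positions=[2, 4])
        assert [e.position for e in events] == [2, 4]
        with pytest.raises(ValueError):
            find_cleavage_sites(rec, positions=[5])

    def test_site_table_physiological_filter(self):
        rec = ProteinRecord(id="p", sequence="AGGKAGG")
        table = pd.DataFrame([
            {"protein_id": "p", "position": "3", "enzyme": "DUB",
             "physiological": "true"},
            {"protein_id": "p", "position": "5", "enzyme": "x",
             "physiological": "false"},
            {"protein_id": "other", "position": "2", "enzyme": "y",
             "physiological": "true"},
        ])
        events = find_cleavage_sites(rec, site_rows=table)
        assert [(e.position, e.enzyme) for e in events] == [(3, "DUB")]
        all_events = find_cleavage_sites(rec, site_rows=table,
                                         skip_non_physiological=False)
        assert [e.position for e in all_events] == [3, 5]

    def test_no_occurrence_empty(self):
        rec = ProteinRecord(id="p", sequence="AAAA")
        assert find_cleavage_sites(rec, rule="Trypsin") == []


class TestDigest:
    def events(self, positions):
        return [CleavageEvent(p, CleavageSource.USER_SITE) for p in positions]

    def test_full_digest_partition(self):
        rec = ProteinRecord(id="p", sequence="AKRPGKA")
        frags = digest(rec, self.events([2, 6]), mode="full")
        assert [(f.start, f.end) for f in frags] == [(1, 2), (3, 6), (7, 7)]
        assert [f.sequence for f in frags] == ["AK", "RPGK", "A"]
        assert [(f.neo_n, f.neo_c) for f in frags] == \
               [(False, True), (True, True), (True, False)]

    def test_empty_events_identity(self):
        rec = ProteinRecord(id="p", sequence="AKRPGKA")
        (f,) = digest(rec, [], mode="full")
        assert (f.start, f.end) == (1, 7)
        assert not f.neo_n and not f.neo_c

    def test_single_site_mode_pairs(self):
        rec = ProteinRecord(id="p", sequence="AKRPGKA")
        frags = digest(rec, self.events([2, 6]), mode="single_site")
        assert [(f.start, f.end) for f in frags] == \
               [(1, 2), (3, 7), (1, 6), (7, 7)]

    def test_conservation_property_fuzz(self, rng):
        """Full-digest fragments are ordered, disjoint and concatenate to
        the parent (500 fuzzed digests)."""
        for _ in range(500):
            seq = random_sequence(rng, 2, 80)
            rec = ProteinRecord(id="p", sequence=seq)
            k = rng.randint(0, min(6, len(seq) - 1))
            cuts = rng.sample(range(1, len(seq)), k)
            frags = digest(rec, self.events(cuts), mode="full")
            assert "".join(f.sequence for f in frags) == seq
            assert all(a.end + 1 == b.start for a, b in zip(frags, frags[1:]))
            assert len(frags) == len(set(cuts)) + 1


class TestNeoDegronScreen:
    def test_neo_n_lysine_flagged_type1(self):
        seq = "A" * 10 + "GG" + "KSDSE"
        rec = ProteinRecord(id="p", sequence=seq)
        ms = make_motif_set(make_motif("nt1", "[RKH]", LocationClass.N_TERMINAL))
        frags = digest(rec, [CleavageEvent(12, CleavageSource.USER_SITE)])
        n_rep, c_rep = neo_degron_screen(frags, ms)
        assert n_rep.neo_n_class is None                 # parent N terminus
        assert c_rep.neo_n_class is NEndClass.TYPE1_PRIMARY
        (m,) = c_rep.neo_n_matches
        assert c_rep.parent_positions[m] == (13, 13)

    def test_neo_c_diglycine_flagged(self):
        seq = "AAAAAGG" + "KAAAA"
        rec = ProteinRecord(id="p", sequence=seq)
        ms = make_motif_set(make_motif("gg", "GG", LocationClass.C_TERMINAL))
        frags = digest(rec, [CleavageEvent(7, CleavageSource.USER_SITE)])
        n_rep, c_rep = neo_degron_screen(frags, ms)
        (m,) = n_rep.neo_c_matches
        assert n_rep.parent_positions[m] == (6, 7)
        assert c_rep.neo_c_matches == ()                 # parent C terminus

    def test_non_neo_termini_not_screened(self):
        rec = ProteinRecord(id="p", sequence="KAAAGG")
        ms = make_motif_set(make_motif("nt1", "[RKH]", LocationClass.N_TERMINAL),
                            make_motif("gg", "GG", LocationClass.C_TERMINAL))
        (rep,) = neo_degron_screen(digest(rec, []), ms)
        assert rep.neo_n_class is None
        assert rep.neo_n_matches == () and rep.neo_c_matches == ()
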