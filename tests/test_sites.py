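import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autocsc.io import AnnotationRecord, ProteinRecord
from autocsc.sites import (
    GlycoSite,
    Proteome,
    SequonSite,
    UnmappablePeptideError,
    assign_sites,
    census,
    compare_to_annotation,
    filter_glycopeptides,
    locate_peptide,
    map_glycosites,
    scan_sequons,
    unique_sites,
)
from conftest import make_obs
from oracles import brute_assignment, brute_sequon_positions

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestScanSequons:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("ANGSK", [SequonSite(2, "NXS")]),
            ("NNSS", [SequonSite(1, "NXS"), SequonSite(2, "NXS")]),  # overlapping
            ("AAN", []),  # motif would extend past the C-terminus
            ("NGT", [SequonSite(1, "NXT")]),
            ("NAC", [SequonSite(1, "NXC")]),
            ("NGA", []),
        ],
    )
    def test_examples(self, sequence, expected):
        assert scan_sequons(sequence) == expected

    def test_proline_x_flag(self):
        assert scan_sequons("ANPSK", exclude_proline_x=True) == []
        assert scan_sequons("ANPSK") == [SequonSite(2, "NXS")]

    def test_restricted_third_residues(self):
        assert scan_sequons("NAC", third_residues="ST") == []

    @settings(max_examples=200, deadline=None)
    @given(
        seq=st.text(alphabet=AA, min_size=0, max_size=60),
        flag=st.booleans(),
    )
    def test_matches_regex_oracle(self, seq, flag):
        got = [s.position for s in scan_sequons(seq, exclude_proline_x=flag)]
        assert got == brute_sequon_positions(seq, exclude_proline_x=flag)


class TestLocatePeptide:
    def test_overlapping_matches(self):
        assert locate_peptide("NGS", ProteinRecord("P", "ANGSNGSK")) == [2, 5]

    def test_no_match(self):
        assert locate_peptide("WWW", ProteinRecord("P", "AAAA")) == []

    def test_identity(self):
        assert locate_peptide("MKR", ProteinRecord("P", "MKR")) == [1]

    def test_periodic_overlap(self):
        assert locate_peptide("AA", "AAAA") == [1, 2, 3]


class TestFilterGlycopeptides:
    def test_retained_when_sequon_and_deamidation(self, tiny_proteome):
        obs = make_obs("NGSIK", deamid_at=[1], accessions=["P2"])
        result = filter_glycopeptides([obs], tiny_proteome)
        assert result.retained == [obs]

    def test_removed_without_sequon(self, tiny_proteome):
        obs = make_obs("NGAIK", deamid_at=[1], accessions=["P2"])
        result = filter_glycopeptides([obs], tiny_proteome)
        assert result.removed == [obs]

    def test_removed_without_deamidation(self, tiny_proteome):
        obs = make_obs("NGSIK", deamid_at=[], accessions=["P2"])
        assert filter_glycopeptides([obs], tiny_proteome).removed == [obs]

    def test_motif_completed_by_protein_context(self):
        # peptide ends at the N; the GS completing the sequon is downstream
        proteome = Proteome([ProteinRecord("P1", "MAAKNGSLLR")])
        obs = make_obs("MAAKN", deamid_at=[5], accessions=["P1"])
        result = filter_glycopeptides([obs], proteome)
        assert result.retained == [obs]

    def test_context_needed_but_unmappable(self, tiny_proteome):
        obs = make_obs("WWWWN", deamid_at=[5], accessions=["P3"])
        result = filter_glycopeptides([obs], tiny_proteome)
        assert result.unmappable == [obs]

    def test_q_value_threshold(self, tiny_proteome):
        kept = make_obs("NGSIK", [1], ["P2"], q_value=0.01)
        dropped = make_obs("NGSIK", [1], ["P2"], q_value=0.02)
        result = filter_glycopeptides([kept, dropped], tiny_proteome)
        assert result.retained == [kept] and result.removed == [dropped]

    def test_missing_q_value_passes(self, tiny_proteome):
        obs = make_obs("NGSIK", [1], ["P2"], q_value=None)
        assert filter_glycopeptides([obs], tiny_proteome).retained == [obs]

    def test_contaminant_prefix_removed(self, tiny_proteome):
        obs = make_obs("NGSIK", [1], ["CON_TRYP"])
        assert filter_glycopeptides([obs], tiny_proteome).removed == [obs]

    def test_deamidated_arginine_does_not_count(self, tiny_proteome):
        # reader tolerates deamidation at R; the filter requires asparagine
        from autocsc.io import Modification

        obs = make_obs("RGSIK", deamid_at=[], accessions=["P1"])
        obs.modifications = [Modification(1, "Deamidated (R)")]
        assert filter_glycopeptides([obs], tiny_proteome).removed == [obs]


class TestMapGlycosites:
    def test_single_mapping(self, tiny_proteome):
        obs = make_obs("NGSIK", [1], ["P2"])
        a = map_glycosites(obs, tiny_proteome)
        assert a.sites == [GlycoSite("P2", 3, "NXS")]
        assert a.proteotypic and a.group_specific
        assert a.assigned_accession == "P2"

    def test_rule_iii_prefers_higher_consensus_count(self):
        # ANG occurs at offsets 2 and 10; only offset 2 puts the deamidated N
        # on a sequon (NGS vs NGA), so rule (iii) keeps offset 2 alone
        protein = ProteinRecord("P1", "MANGSKWWWANGAKWW")
        obs = make_obs("ANG", [2], ["P1"])
        a = map_glycosites(obs, Proteome([protein]))
        assert a.sites == [GlycoSite("P1", 3, "NXS")]

    def test_rule_iii_tie_keeps_both(self):
        protein = ProteinRecord("P1", "MANGSKWANGSKW")
        obs = make_obs("ANGSK", [2], ["P1"])
        a = map_glycosites(obs, Proteome([protein]))
        assert a.sites == [GlycoSite("P1", 3, "NXS"), GlycoSite("P1", 9, "NXS")]

    def test_lexicographic_tiebreak(self):
        proteome = Proteome(
            [ProteinRecord("P9", "MNGSIKR"), ProteinRecord("P2", "MNGSIKR")]
        )
        obs = make_obs("NGSIK", [1], ["P9", "P2"])
        a = map_glycosites(obs, proteome)
        assert a.assigned_accession == "P2"
        assert not a.proteotypic and a.group_specific

    def test_non_group_specific_flagged(self):
        proteome = Proteome(
            [ProteinRecord("P1", "MNGSIKR"), ProteinRecord("P2", "MNGSIKR")]
        )
        obs = make_obs("NGSIK", [1], ["P1"])  # also matches P2, outside group
        a = map_glycosites(obs, proteome)
        assert not a.group_specific

    def test_unmappable_raises(self, tiny_proteome):
        with pytest.raises(UnmappablePeptideError):
            map_glycosites(make_obs("WWWWWW", [], ["P1"]), tiny_proteome)

    def test_assign_sites_collects_unmappable(self, tiny_proteome):
        good = make_obs("NGSIK", [1], ["P2"])
        bad = make_obs("WWWWWW", [], ["P1"])
        assignments, unmappable = assign_sites([good, bad], tiny_proteome)
        assert len(assignments) == 1 and unmappable == [bad]

    def test_emitted_sites_satisfy_sequon_in_protein(self, tiny_proteome):
        obs = make_obs("ANKTAAR", [2], ["P1"])
        a = map_glycosites(obs, tiny_proteome)
        for s in a.sites:
            seq = tiny_proteome[s.accession].sequence
            assert seq[s.position - 1] == "N"
            assert seq[s.position + 1] in "STC"


class TestRuleIIIOracle:
    """Randomized multi-mapping peptides vs. the brute-force rule enumerator."""

    def _random_case(self, rng):
        n_prot = int(rng.integers(2, 8))
        seqs = {
            f"Q{i}": "".join(rng.choice(list(AA), size=int(rng.integers(40, 90))))
            for i in range(n_prot)
        }
        # implant one peptide into 1-3 random places across random proteins
        host = f"Q{int(rng.integers(n_prot))}"
        hseq = seqs[host]
        plen = int(rng.integers(6, 13))
        start = int(rng.integers(0, len(hseq) - plen))
        pep = hseq[start : start + plen]
        for _ in range(int(rng.integers(0, 3))):
            tgt = f"Q{int(rng.integers(n_prot))}"
            tseq = seqs[tgt]
            pos = int(rng.integers(0, len(tseq) - plen))
            seqs[tgt] = tseq[:pos] + pep + tseq[pos + plen :]
        ns = [i + 1 for i, ch in enumerate(pep) if ch == "N"]
        deamid = sorted(rng.choice(ns, size=min(len(ns), 2), replace=False)) if ns else []
        proteome = {a: s for a, s in seqs.items()}
        group = sorted(a for a, s in proteome.items() if pep in s)
        return proteome, pep, [int(p) for p in deamid], group

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 300:
            proteome, pep, deamid, group = self._random_case(rng)
            if not group or not deamid:
                continue
            checked += 1
            obs = make_obs(pep, deamid, group)
            prot = Proteome([ProteinRecord(a, s) for a, s in proteome.items()])
            a = map_glycosites(obs, prot)
            expected = brute_assignment(pep, deamid, group, proteome)
            assert expected is not None
            acc, sites = expected
            assert a.assigned_accession == acc
            assert {(s.position, s.motif_class) for s in a.sites} == sites


class TestCensus:
    def test_same_site_counted_once(self, tiny_proteome):
        a1 = map_glycosites(make_obs("NGSIK", [1], ["P2"]), tiny_proteome)
        a2 = map_glycosites(make_obs("NGSIKLLR", [1], ["P2"]), tiny_proteome)
        c = census([a1, a2])
        assert c.n_sites == 1 and c.n_protein_groups == 1

    def test_median_by_hand(self):
        proteome = Proteome(
            [
                ProteinRecord("A1", "MNGSKNGTKNGSWNGTWNGCWR"),
                ProteinRecord("B1", "MMNGSKR"),
                ProteinRecord("C1", "MMNGSKWNGTKR"),
            ]
        )
        # groups with unique-site counts {1, 2, 5}
        a_sites = [
            map_glycosites(make_obs(pep, d, ["A1"]), proteome)
            for pep, d in [("NGSKNGTK", [1, 5]), ("NGSWNGTWNGCWR", [1, 5, 9])]
        ]
        b_sites = [map_glycosites(make_obs("NGSKR", [1], ["B1"]), proteome)]
        c_sites = [map_glycosites(make_obs("NGSKWNGTKR", [1, 6], ["C1"]), proteome)]
        c = census(a_sites + b_sites + c_sites)
        assert sorted(c.sites_per_group.values()) == [1, 2, 5]
        assert c.median_sites_per_group == 2.0
        assert c.n_sites == 8

    def test_invariant_to_order_and_duplicates(self, tiny_proteome):
        obs = [
            make_obs("NGSIK", [1], ["P2"]),
            make_obs("ANKTAAR", [2], ["P1"]),
            make_obs("ANGSK", [2], ["P1"]),
        ]
        a, _ = assign_sites(obs, tiny_proteome)
        base = census(a)
        shuffled = census(list(reversed(a)))
        doubled = census(a + a)
        for other in (shuffled, doubled):
            assert other.n_sites == base.n_sites
            assert other.sites_per_group == base.sites_per_group

    def test_empty_census(self):
        c = census([])
        assert c.n_sites == 0 and c.median_sites_per_group is None

    def test_n_sites_equals_group_sum_when_disjoint(self, tiny_proteome):
        obs = [
            make_obs("NGSIK", [1], ["P2"]),
            make_obs("ANKTAAR", [2], ["P1"]),
        ]
        a, _ = assign_sites(obs, tiny_proteome)
        c = census(a)
        assert c.n_sites == sum(c.sites_per_group.values())


class TestCompareToAnnotation:
    def test_confirmed_predicted(self):
        out = compare_to_annotation(
            [GlycoSite("P1", 10, "NXS")], [AnnotationRecord("P1", 10, "predicted")]
        )
        assert out == {
            "novel": 0,
            "confirmed_experimental": 0,
            "confirmed_predicted": 1,
            "annotated_not_observed": 0,
        }

    def test_annotation_on_unobserved_protein_ignored(self):
        out = compare_to_annotation(
            [GlycoSite("P1", 10, "NXS")], [AnnotationRecord("P2", 10, "experimental")]
        )
        assert out["novel"] == 1 and out["annotated_not_observed"] == 0

    def test_empty_annotation_all_novel(self):
        sites = [GlycoSite("P1", 10, "NXS"), GlycoSite("P1", 30, "NXT")]
        assert compare_to_annotation(sites, [])["novel"] == 2

    def test_annotated_not_observed_counts_observed_proteins_only(self):
        out = compare_to_annotation(
            [GlycoSite("P1", 10, "NXS")],
            [
                AnnotationRecord("P1", 10, "experimental"),
                AnnotationRecord("P1", 50, "predicted"),
                AnnotationRecord("P2", 7, "predicted"),
            ],
        )
        assert out["annotated_not_observed"] == 1


class TestUniqueSites:
    def test_proteotypic_only_restriction(self):
        proteome = Proteome(
            [ProteinRecord("P1", "MNGSIKR"), ProteinRecord("P2", "MNGSIKRW")]
        )
        shared = make_obs("NGSIK", [1], ["P1", "P2"])
        a, _ = assign_sites([shared], proteome)
        assert unique_sites(a, proteotypic_only=False) == [GlycoSite("P1", 2, "NXS")]
        assert unique_sites(a, proteotypic_only=True) == []
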