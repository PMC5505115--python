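"""Gap-tolerant homology mapping and parsimony protein inference."""

import itertools

import numpy as np
import pytest

from metacontig.constants import RESIDUE_MASS
from metacontig.denovo import parse_denovo_string
from metacontig.homology import (
    HomologyMatch,
    align_denovo_to_protein,
    bundled_contaminants,
    filter_contaminants,
    parsimony_group,
    search_database,
)
from metacontig.model import ProteinRecord


def protein(acc, seq):
    return ProteinRecord(accession=acc, description="test", sequence=seq)


class TestAlign:
    def test_exact_substring(self):
        seq = parse_denovo_string("PEPTIDE", "c1")
        m = align_denovo_to_protein(seq, protein("P1", "MKPEPTIDER"))
        assert m is not None
        assert (m.start, m.end) == (2, 9)
        assert m.matched_residues == 7

    def test_gap_consumes_matching_substring(self):
        seq = parse_denovo_string("PE[198.1]IDE", "c1")
        m = align_denovo_to_protein(seq, protein("P1", "MKPEPTIDER"), min_matched=5)
        assert m is not None
        assert m.matched_residues == 5
        assert len(m.gap_spans) == 1
        gap_idx, (s, e) = m.gap_spans[0]
        assert gap_idx == 2
        # the consumed substring is PT, whose residue masses sum to ~198.100
        consumed = "MKPEPTIDER"[s:e]
        assert consumed == "PT"
        assert abs(sum(RESIDUE_MASS[a] for a in consumed) - 198.1) < 0.05

    def test_unsatisfiable_gap(self):
        seq = parse_denovo_string("PE[500.0]IDE", "c1")
        assert align_denovo_to_protein(seq, protein("P1", "MKPEPTIDER"), min_matched=5) is None

    def test_isoleucine_leucine_equivalence(self):
        seq = parse_denovo_string("PEPTIDEI", "c1")
        m = align_denovo_to_protein(seq, protein("P1", "XPEPTIDELK".replace("X", "M")), min_matched=6)
        assert m is not None and m.matched_residues == 8

    def test_min_matched_threshold(self):
        seq = parse_denovo_string("PEP", "c1")
        assert align_denovo_to_protein(seq, protein("P1", "MKPEPTIDER")) is None

    def test_gap_span_mass_recomputed(self):
        """Every reported gap span satisfies its mass constraint."""
        p = protein("P1", "MKWPEPTIDEGASRPK")
        gap = sum(RESIDUE_MASS[a] for a in "GAS")
        seq = parse_denovo_string(f"PEPTIDE[{gap:.3f}]RPK", "c1")
        m = align_denovo_to_protein(seq, p, min_matched=5)
        assert m is not None
        for gap_idx, (s, e) in m.gap_spans:
            total = sum(RESIDUE_MASS[a] for a in p.sequence[s:e])
            assert abs(total - seq.elements[gap_idx].mass) <= 0.05


class TestSearch:
    def test_single_hit(self):
        seqs = [parse_denovo_string("PEPTIDE", "c1")]
        db = [protein("P1", "MKPEPTIDER"), protein("P2", "WWWWWWWWWW")]
        matches = search_database(seqs, db)
        assert [(m.accession, m.best) for m in matches] == [("P1", True)]

    def test_isoform_tie_broken_by_accession(self):
        seqs = [parse_denovo_string("PEPTIDE", "c1")]
        db = [protein("PB", "MKPEPTIDER"), protein("PA", "GGPEPTIDEK")]
        matches = search_database(seqs, db)
        assert len(matches) == 2
        assert matches[0].accession == "PA" and matches[0].best
        assert matches[1].accession == "PB" and not matches[1].best

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            search_database([parse_denovo_string("PEPTIDE", "c1")], [])

    def test_removing_other_protein_keeps_score(self):
        seqs = [parse_denovo_string("PEPTIDE", "c1")]
        db = [protein("P1", "MKPEPTIDER"), protein("P2", "AAPEPTIDEA")]
        full = {m.accession: m.score for m in search_database(seqs, db)}
        reduced = {m.accession: m.score for m in search_database(seqs, db[:1])}
        assert reduced["P1"] == full["P1"]


class TestContaminants:
    def make_match(self, cid, acc):
        return HomologyMatch(
            contig_id=cid, accession=acc, start=0, end=7,
            matched_residues=7, gap_spans=[], score=7.0, best=True,
        )

    def test_bundled_protease_removed(self):
        assert "TRYP_PIG" in bundled_contaminants()
        kept, removed = filter_contaminants(
            [self.make_match("c1", "TRYP_PIG"), self.make_match("c2", "P1")]
        )
        assert [m.accession for m in kept] == ["P1"]
        assert [m.accession for m in removed] == ["TRYP_PIG"]

    def test_empty_list_is_identity(self):
        matches = [self.make_match("c1", "TRYP_PIG")]
        kept, removed = filter_contaminants(matches, set())
        assert kept == matches and removed == []

    def test_partition(self):
        matches = [self.make_match(f"c{i}", acc) for i, acc in
                   enumerate(["P1", "K1C9_HUMAN", "P2", "PEPA_PIG"])]
        kept, removed = filter_contaminants(matches)
        assert len(kept) + len(removed) == len(matches)


def brute_force_min_cover(contigs_of):
    """Smallest accession set covering all contigs, by exhaustive search."""
    contigs = set().union(*contigs_of.values())
    accs = sorted(contigs_of)
    for size in range(1, len(accs) + 1):
        for combo in itertools.combinations(accs, size):
            if set().union(*(contigs_of[a] for a in combo)) >= contigs:
                return size
    return len(accs)


class TestParsimony:
    def make_matches(self, contig_to_accs):
        out = []
        for cid, accs in contig_to_accs.items():
            for acc in accs:
                out.append(
                    HomologyMatch(
                        contig_id=cid, accession=acc, start=0, end=7,
                        matched_residues=7, gap_spans=[], score=7.0,
                    )
                )
        return out

    def test_hand_worked_cover(self):
        matches = self.make_matches(
            {"c1": {"P1", "P2"}, "c2": {"P1"}, "c3": {"P1", "P3"}}
        )
        report = parsimony_group(matches)
        assert report.selected == ["P1"]

    def test_unique_mappings_select_all(self):
        matches = self.make_matches({"c1": {"P1"}, "c2": {"P2"}, "c3": {"P3"}})
        report = parsimony_group(matches)
        assert report.selected == ["P1", "P2", "P3"]

    def test_every_contig_supported(self, rng):
        for _ in range(20):
            contig_to_accs = {
                f"c{i}": set(rng.choice([f"P{j}" for j in range(6)],
                                        size=int(rng.integers(1, 4)), replace=False))
                for i in range(int(rng.integers(2, 10)))
            }
            report = parsimony_group(self.make_matches(contig_to_accs))
            covered = set().union(*(set(report.support[a]) for a in report.selected))
            assert covered == set(contig_to_accs)

    def test_greedy_close_to_exhaustive_cover(self, rng):
        for _ in range(20):
            contig_to_accs = {
                f"c{i}": set(rng.choice([f"P{j}" for j in range(8)],
                                        size=int(rng.integers(1, 4)), replace=False))
                for i in range(int(rng.integers(3, 10)))
            }
            accs_to_contigs = {}
            for cid, accs in contig_to_accs.items():
                for a in accs:
                    accs_to_contigs.setdefault(a, set()).add(cid)
            report = parsimony_group(self.make_matches(contig_to_accs))
            optimum = brute_force_min_cover(accs_to_contigs)
            n = len(contig_to_accs)
            assert len(report.selected) <= max(optimum, int(np.ceil(optimum * np.log(n) + 1e-9)))

    def test_no_matches_rejected(self):
        with pytest.raises(ValueError):
            parsimony_group([])
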