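"""Synthetic proteome, digestion, fragmentation and acquisition simulation."""

import numpy as np
import pytest
from scipy import stats

from metacontig import simulate
from metacontig.constants import PROTON, RESIDUE_MASS, WATER, peptide_mass
from metacontig.simulate import (
    CHYMOTRYPSIN,
    PEPSIN,
    TRYPSIN,
    DigestSpec,
    FragmentationModel,
    default_digests,
    digest,
    digest_pools,
    eligible_charge,
    fractionate,
    generate_proteome,
    protein_mass,
    simulate_acquisition,
    simulate_triple,
    theoretical_ions,
)
from metacontig.model import ProteinRecord

from conftest import AA, random_peptide


class TestProteome:
    def test_deterministic_under_seed(self):
        a = generate_proteome(3, (60, 100), seed=5)
        b = generate_proteome(3, (60, 100), seed=5)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_lengths_within_bounds(self):
        records = generate_proteome(10, (60, 200), seed=0)
        assert len(records) == 10
        assert all(60 <= len(r) <= 200 for r in records)

    def test_residue_frequencies_uniform(self):
        records = generate_proteome(60, (150, 200), seed=1)
        residues = "".join(r.sequence for r in records)
        assert len(residues) >= 10_000
        counts = [residues.count(a) for a in AA]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_len_range_too_small(self):
        with pytest.raises(ValueError):
            generate_proteome(1, (2, 3), seed=0)


class TestFractionate:
    def test_polyglycine_mass_oracle(self):
        rec = ProteinRecord("G200", sequence="G" * 200)
        expected = 200 * RESIDUE_MASS["G"] + WATER
        assert abs(protein_mass(rec) - expected) < 1e-6
        above, below = fractionate([rec], 10_000.0)
        assert above == [rec] and below == []

    def test_empty_input(self):
        assert fractionate([], 10_000.0) == ([], [])

    def test_partition_property(self, rng):
        records = generate_proteome(20, (60, 120), seed=2)
        above, below = fractionate(records, 9_000.0)
        assert len(above) + len(below) == len(records)
        assert {r.accession for r in above} | {r.accession for r in below} == {
            r.accession for r in records
        }
        assert all(protein_mass(r) > 9_000.0 for r in above)
        assert all(protein_mass(r) <= 9_000.0 for r in below)


class TestDigest:
    def test_trypsin_rule_application(self):
        spec = DigestSpec("t", TRYPSIN, max_missed=0, len_min=4, len_max=30)
        raw = digest("AKRPGKR", spec, length_filter=False)
        assert raw == [("AK", 0), ("RPGK", 2), ("R", 6)]
        assert digest("AKRPGKR", spec) == [("RPGK", 2)]

    def test_p_cleave_one_matches_deterministic(self, rng):
        seq = random_peptide(rng, 40, 60)
        spec = DigestSpec("t", TRYPSIN, p_cleave=1.0, max_missed=0)
        stoch = digest(seq, spec, rng=np.random.default_rng(0), length_filter=False)
        det = digest(seq, spec, length_filter=False)
        assert stoch == det

    def test_p_cleave_zero_whole_protein(self, rng):
        seq = random_peptide(rng, 30, 40)
        spec = DigestSpec("t", TRYPSIN, p_cleave=0.0)
        out = digest(seq, spec, rng=np.random.default_rng(0), length_filter=False)
        assert out == [(seq, 0)]

    def test_zero_missed_products_tile_protein(self, rng):
        for rule in (TRYPSIN, CHYMOTRYPSIN, PEPSIN):
            seq = random_peptide(rng, 50, 80)
            spec = DigestSpec("d", rule, max_missed=0)
            prods = digest(seq, spec, length_filter=False)
            assert "".join(p for p, _ in prods) == seq
            starts = [a for _, a in prods]
            assert starts == sorted(starts)

    def test_unknown_residue(self):
        spec = DigestSpec("t", TRYPSIN)
        with pytest.raises(ValueError):
            digest("PEPXTIDE", spec)


class TestTheoreticalIons:
    def test_ag_cid_b1_y1(self):
        peaks = theoretical_ions("AG", "CID")
        mzs = sorted(p.mz for p in peaks)
        assert any(abs(m - 72.04439) < 1e-5 for m in mzs)  # b1 = A + proton
        assert any(abs(m - 76.03930) < 1e-5 for m in mzs)  # y1 = G + water + proton

    def test_single_residue_no_ions(self):
        assert theoretical_ions("A", "CID") == []

    def test_carbamidomethyl_cysteine(self):
        mzs = [p.mz for p in theoretical_ions("CG", "CID")]
        b1 = 103.00919 + 57.02146 + PROTON  # alkylated cysteine
        assert any(abs(m - b1) < 1e-4 for m in mzs)

    def test_by_complementarity(self, rng):
        """(b_k - proton) + (y_{n-k} - proton) equals the neutral peptide mass."""
        model = FragmentationModel()
        for _ in range(200):
            pep = random_peptide(rng, 4, 18)
            n = len(pep)
            prefix = np.cumsum([RESIDUE_MASS[a] for a in pep])
            neutral = prefix[-1] + WATER
            for k in range(1, n):
                b_k = prefix[k - 1] + PROTON
                y_nk = (prefix[-1] - prefix[k - 1]) + WATER + PROTON
                assert abs((b_k - PROTON) + (y_nk - PROTON) - neutral) < 1e-9


class TestSimulateTriple:
    def test_noiseless_equals_theoretical(self, noiseless_model, rng):
        pep = "PEPTIDER"
        t = simulate_triple(pep, 2, noiseless_model, np.random.default_rng(0))
        for mode, s in zip(("CID", "HCD", "ETD"), t.spectra):
            expected = theoretical_ions(pep, mode, noiseless_model)
            np.testing.assert_allclose(s.mz, sorted(p.mz for p in expected), atol=1e-9)

    def test_seeded_bitwise_reproducible(self):
        model = FragmentationModel()
        t1 = simulate_triple("PEPTIDER", 2, model, np.random.default_rng(7))
        t2 = simulate_triple("PEPTIDER", 2, model, np.random.default_rng(7))
        for a, b in zip(t1.spectra, t2.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_zero_detection_only_noise(self):
        from dataclasses import replace

        base = FragmentationModel()
        model = FragmentationModel(
            {
                mode: replace(
                    mm, series=tuple(replace(s, p_detect=0.0) for s in mm.series)
                )
                for mode, mm in base.modes.items()
            }
        )
        t = simulate_triple("PEPTIDER", 2, model, np.random.default_rng(1))
        theo = {round(p.mz, 2) for p in theoretical_ions("PEPTIDER", "CID")}
        assert not theo & {round(m, 2) for m in t.cid.mz}

    def test_precursor_mass_invariant(self, noiseless_model, rng):
        for _ in range(50):
            pep = random_peptide(rng, 6, 25)
            z = eligible_charge(pep)
            if z is None:
                continue
            t = simulate_triple(pep, z, noiseless_model, np.random.default_rng(0))
            assert abs(t.cid.neutral_mass - peptide_mass(pep)) < 1e-4


class TestAcquisition:
    def test_single_peptide_one_triple(self, noiseless_model):
        pools = {"trypsin_18h": [("PEPTIDER", "P1", 0, 1.0)]}
        triples, gt = simulate_acquisition(pools, noiseless_model, seed=0)
        assert len(triples["trypsin_18h"]) == 1
        assert len(gt) == 1
        assert gt.iloc[0].peptide == "PEPTIDER"

    def test_low_mass_window_exclusion(self, noiseless_model):
        # 4 glycines at 2+ sit near m/z 124, far below the 350-1,800 window
        assert eligible_charge("GGGG") is None
        pools = {
            "trypsin_18h": [("GGGG", "P1", 0, 1.0), ("PEPTIDER", "P1", 10, 1.0)]
        }
        triples, gt = simulate_acquisition(pools, noiseless_model, seed=0)
        assert list(gt.peptide) == ["PEPTIDER"]

    def test_dda_top3_with_exclusion(self, noiseless_model):
        # three co-eluting peptides, top-3 selection: each acquired exactly once
        pools = {
            "trypsin_18h": [
                ("PEPTIDER", "P1", 0, 3.0),
                ("AKAKAKAKAK", "P1", 20, 2.0),
                ("WWHHKKRR", "P1", 40, 1.0),
            ]
        }
        triples, gt = simulate_acquisition(
            pools, noiseless_model, seed=0, dda=True, gradient_s=100.0
        )
        counts = gt.groupby("peptide").size()
        assert set(counts.index) == {"PEPTIDER", "AKAKAKAKAK", "WWHHKKRR"}
        # 60 s exclusion spans most of the 100 s gradient: at most 2 triples each
        assert counts.max() <= 2

    def test_empty_pool_rejected(self, noiseless_model):
        with pytest.raises(ValueError):
            simulate_acquisition({"trypsin_18h": []}, noiseless_model, seed=0)


def test_default_digests_match_study_design():
    names = [d.name for d in default_digests()]
    assert names == ["trypsin_4h", "trypsin_18h", "chymotrypsin_18h", "pepsin_18h"]
    tryp4, tryp18 = default_digests()[:2]
    assert tryp4.p_cleave < tryp18.p_cleave  # 4 h partial vs 18 h
    assert tryp4.rule is TRYPSIN and tryp18.rule is TRYPSIN
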