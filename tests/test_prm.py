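"""PRM transform and triple-merge behaviour."""

import numpy as np
import pytest

from metacontig import simulate
from metacontig.constants import PROTON, RESIDUE_MASS, WATER
from metacontig.model import PRMSpectrum, Spectrum
from metacontig.network import filter_peaks
from metacontig.prm import (
    MODE_BITS,
    ScoringModel,
    merge_triple,
    spectrum_to_prm,
    triple_to_prm,
)

from conftest import random_peptide


def ag_spectrum(mz_values, mode="CID"):
    M_ag = RESIDUE_MASS["A"] + RESIDUE_MASS["G"]  # 128.05857
    pmz = (M_ag + WATER + 2 * PROTON) / 2
    return Spectrum(
        spectrum_id="ag", source_file="t", scan=1, precursor_mz=pmz,
        precursor_charge=2, mode=mode,
        mz=np.array(mz_values), intensity=np.ones(len(mz_values)),
    )


class TestSpectrumToPRM:
    def test_b1_only(self):
        prm = spectrum_to_prm(ag_spectrum([72.04439]))
        assert np.any(np.abs(prm.masses - 71.03711) < 1e-4)

    def test_y1_corroborates_same_prm_mass(self):
        # y1 of "AG" read C-terminally lands on the same prefix mass as b1
        prm = spectrum_to_prm(ag_spectrum([76.03930]))
        assert np.any(np.abs(prm.masses - 71.03711) < 1e-4)

    def test_empty_peak_list(self):
        prm = spectrum_to_prm(ag_spectrum([]))
        assert len(prm) == 0

    def test_masses_inside_open_interval(self, rng):
        for _ in range(30):
            pep = random_peptide(rng, 6, 20)
            z = simulate.eligible_charge(pep)
            if z is None:
                continue
            t = simulate.simulate_triple(
                pep, z, simulate.FragmentationModel(), np.random.default_rng(1)
            )
            for s in t.spectra:
                prm = spectrum_to_prm(s)
                if len(prm):
                    assert prm.masses[0] > 0 and prm.masses[-1] < prm.M
                    assert np.all(np.diff(prm.masses) > 0)

    def test_unknown_mode_rejected(self):
        s = ag_spectrum([72.0])
        s.mode = "CID"
        model = ScoringModel(priors={"HCD": {"b": 0.5, "y": 0.5}})
        with pytest.raises(ValueError):
            spectrum_to_prm(s, model)


def prm_of(masses, scores, M=1000.0, sid="p", mode="CID"):
    return PRMSpectrum(
        spectrum_id=sid, M=M, masses=np.asarray(masses, float),
        scores=np.asarray(scores, float), provenance=(mode,),
        peak_modes=np.full(len(masses), MODE_BITS[mode], dtype=np.uint8),
    )


class TestMergeTriple:
    def test_three_copies_add(self):
        parts = [
            prm_of([200.0], [1.0], sid=f"x.{m}", mode=m) for m in ("CID", "HCD", "ETD")
        ]
        merged = merge_triple(parts)
        assert len(merged) == 1
        assert abs(merged.masses[0] - 200.0) < 1e-9
        assert abs(merged.scores[0] - 3.0) < 1e-12
        assert merged.peak_modes[0] == 7

    def test_cluster_split_rule(self):
        parts = [
            prm_of([200.00], [1.0], mode="CID"),
            prm_of([200.60], [1.0], mode="HCD"),
            prm_of([], [], mode="ETD"),
        ]
        merged = merge_triple(parts, merge_tol=0.3)
        assert len(merged) == 2

    def test_score_conservation_random(self, rng):
        for _ in range(200):
            parts = []
            M = float(rng.uniform(600, 2000))
            for mode in ("CID", "HCD", "ETD"):
                n = int(rng.integers(0, 30))
                masses = np.unique(rng.uniform(1, M - 1, n).round(4))
                scores = rng.uniform(0.1, 8.0, masses.size)
                parts.append(prm_of(masses, scores, M=M, mode=mode))
            merged = merge_triple(parts)
            assert abs(merged.total_score - sum(p.total_score for p in parts)) < 1e-9

    def test_permutation_invariance(self, rng):
        M = 1500.0
        parts = [
            prm_of(np.unique(rng.uniform(1, M - 1, 12).round(3)),
                   rng.uniform(0.5, 5.0, 12)[:12], M=M, mode=m)
            for m in ("CID", "HCD", "ETD")
        ]
        parts = [
            prm_of(p.masses, p.scores[: len(p)], M=M, mode=m)
            for p, m in zip(parts, ("CID", "HCD", "ETD"))
        ]
        a = merge_triple(parts)
        b = merge_triple(parts[::-1])
        np.testing.assert_allclose(a.masses, b.masses, atol=1e-9)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)

    def test_precursor_mismatch_rejected(self):
        parts = [
            prm_of([100.0], [1.0], M=1000.0, mode="CID"),
            prm_of([100.0], [1.0], M=1002.0, mode="HCD"),
            prm_of([100.0], [1.0], M=1000.0, mode="ETD"),
        ]
        with pytest.raises(ValueError):
            merge_triple(parts)


@pytest.fixture(scope="module")
def merged_cases():
    model = simulate.FragmentationModel().noiseless()
    rng = np.random.default_rng(77)
    rng_pep = np.random.default_rng(5)
    cases = []
    for _ in range(40):
        pep = random_peptide(rng_pep, 6, 22)
        z = simulate.eligible_charge(pep)
        if z is None:
            continue
        t = simulate.simulate_triple(pep, z, model, rng)
        cases.append((pep, triple_to_prm(t)))
    return cases


class TestNoiselessTriple:
    """The merged PRM spectrum of a noiseless triple: every true prefix mass is
    present and carries corroboration from all three dissociation modes, which
    no spurious interpretation achieves."""

    def test_every_true_prefix_present(self, merged_cases):
        for pep, merged in merged_cases:
            true = np.cumsum([RESIDUE_MASS[a] for a in pep])[:-1]
            for tm in true:
                assert np.min(np.abs(merged.masses - tm)) < 0.3

    def test_three_mode_corroboration_separates_true_from_spurious(self, merged_cases):
        for pep, merged in merged_cases:
            true = np.cumsum([RESIDUE_MASS[a] for a in pep])[:-1]
            kept = filter_peaks(merged, min_modes=3)
            assert len(kept) == len(true)
            # a coincident single-interpretation mass occasionally merges into
            # a true cluster and pulls the score-weighted mean by < 0.1 Da
            np.testing.assert_allclose(np.sort(kept.masses), true, atol=0.1)

    def test_true_prefixes_outscore_single_mode_spurious(self, merged_cases):
        for pep, merged in merged_cases:
            true = np.cumsum([RESIDUE_MASS[a] for a in pep])[:-1]
            is_true = np.array(
                [np.min(np.abs(true - m)) < 0.3 for m in merged.masses]
            )
            if is_true.all():
                continue
            popcount = np.array([bin(int(b)).count("1") for b in merged.peak_modes])
            # no spurious mass ever reaches three-mode corroboration, and every
            # true prefix outscores every single-interpretation spurious mass
            assert popcount[~is_true].max() < 3
            singles = merged.scores[~is_true & (popcount == 1)]
            if len(singles):
                assert merged.scores[is_true].min() > singles.max()
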