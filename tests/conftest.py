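import numpy as np
import pytest

from metacontig import simulate
from metacontig.constants import RESIDUE_MASS
from metacontig.model import PRMSpectrum
from metacontig.pipeline import PipelineConfig, run_pipeline

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def noiseless_model():
    return simulate.FragmentationModel().noiseless()


def random_peptide(rng, n_min=6, n_max=20):
    n = int(rng.integers(n_min, n_max + 1))
    return "".join(rng.choice(list(AA), size=n))


def ideal_prm(peptide: str, spectrum_id: str = "", score: float = 10.0) -> PRMSpectrum:
    """Noise-free PRM ladder of a peptide: every internal prefix mass."""
    masses = np.cumsum([RESIDUE_MASS[a] for a in peptide])
    return PRMSpectrum(
        spectrum_id=spectrum_id or peptide,
        M=float(masses[-1]),
        masses=masses[:-1].astype(float),
        scores=np.full(len(peptide) - 1, score),
        provenance=("CID", "HCD", "ETD"),
        peak_modes=np.full(len(peptide) - 1, 7, dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """The reference noiseless study: 10 proteins of 60-200 residues, the four
    digest conditions, noiseless CID/HCD/ETD triples."""
    cfg = PipelineConfig(
        seed=11, n_proteins=10, len_range=(60, 200),
        noiseless=True, deterministic_digests=True,
    )
    out = tmp_path_factory.mktemp("study_run")
    return run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A fast noiseless run used by pipeline/reporting tests."""
    cfg = PipelineConfig(
        seed=3, n_proteins=4, len_range=(60, 110),
        noiseless=True, deterministic_digests=True,
    )
    out = tmp_path_factory.mktemp("small_run")
    return run_pipeline(cfg, out)
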