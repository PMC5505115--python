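"""Core spectral data model.

The pipeline's currency is, in order of processing: centroided MS/MS scans
(:class:`Spectrum`), CID/HCD/ETD co-precursor triples (:class:`SpectrumTriple`),
and scored prefix-residue-mass spectra (:class:`PRMSpectrum`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .constants import MODES, PROTON, WATER


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided MS/MS scan with its fragmentation mode.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z.
    """

    spectrum_id: str
    source_file: str
    scan: int
    precursor_mz: float
    precursor_charge: int
    mode: str
    mz: np.ndarray
    intensity: np.ndarray
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 1 <= int(self.precursor_charge) <= 5:
            raise ValueError(f"precursor charge {self.precursor_charge} outside 1-5")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("peaks must have mz > 0 and intensity >= 0")
        if self.neutral_mass <= 0:
            raise ValueError("non-positive neutral precursor mass")

    @property
    def neutral_mass(self) -> float:
        """Neutral precursor mass M+H2O: mz*z - z*proton."""
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON

    @property
    def residue_mass_total(self) -> float:
        """Total residue mass M (neutral precursor minus water)."""
        return self.neutral_mass - WATER

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectrumTriple:
    """CID, HCD and ETD scans acquired from one precursor."""

    cid: Spectrum
    hcd: Spectrum
    etd: Spectrum
    triple_id: str = ""

    def __post_init__(self) -> None:
        expected = {"cid": "CID", "hcd": "HCD", "etd": "ETD"}
        for name, mode in expected.items():
            s = getattr(self, name)
            if s.mode != mode:
                raise ValueError(f"{name} slot holds a {s.mode} spectrum")
        charges = {s.precursor_charge for s in self.spectra}
        if len(charges) != 1:
            raise ValueError(f"triple spans charges {sorted(charges)}")
        if not self.triple_id:
            tid = self.cid.spectrum_id
            self.triple_id = tid[:-4] if tid.endswith(".CID") else tid

    @property
    def spectra(self) -> tuple[Spectrum, Spectrum, Spectrum]:
        return (self.cid, self.hcd, self.etd)

    @property
    def precursor_mz(self) -> float:
        return self.cid.precursor_mz

    @property
    def precursor_charge(self) -> int:
        return self.cid.precursor_charge

    def validate(self, precursor_tol: float = 0.01) -> None:
        mzs = [s.precursor_mz for s in self.spectra]
        if max(mzs) - min(mzs) > precursor_tol:
            raise ValueError(
                f"triple {self.triple_id}: precursor m/z spread "
                f"{max(mzs) - min(mzs):.4f} exceeds {precursor_tol}"
            )


@dataclass
class ProteinRecord:
    accession: str
    description: str = ""
    sequence: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PRMSpectrum:
    """Scored prefix-residue-mass spectrum.

    ``masses`` are hypothesized cumulative N-terminal residue masses in the
    open interval (0, M); the boundary masses 0 and M are implicit and never
    stored.  ``scores`` are additive log-odds.  ``provenance`` lists the
    fragmentation modes that contributed.
    """

    spectrum_id: str
    M: float
    masses: np.ndarray
    scores: np.ndarray
    provenance: tuple[str, ...] = ()
    #: per-peak bitmask of contributing modes (CID=1, HCD=2, ETD=4); None
    #: when the spectrum predates merging or provenance was not tracked
    peak_modes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.masses.shape != self.scores.shape:
            raise ValueError("masses and scores differ in length")
        if self.peak_modes is not None:
            self.peak_modes = np.asarray(self.peak_modes, dtype=np.uint8)
            if self.peak_modes.shape != self.masses.shape:
                raise ValueError("peak_modes and masses differ in length")
        if self.masses.size:
            if np.any(np.diff(self.masses) <= 0):
                raise ValueError("PRM masses must be strictly increasing")
            if self.masses[0] <= 0 or self.masses[-1] >= self.M:
                raise ValueError("PRM masses must lie strictly inside (0, M)")

    def __len__(self) -> int:
        return int(self.masses.size)

    @property
    def total_score(self) -> float:
        return float(self.scores.sum())


def sorted_peak_arrays(
    peaks: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Split (mz, intensity) pairs into sorted parallel arrays."""
    if not len(peaks):
        return np.empty(0), np.empty(0)
    arr = np.asarray(peaks, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    return arr[order, 0], arr[order, 1]
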