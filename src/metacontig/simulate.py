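"""Synthetic venom proteome and acquisition simulator.

Emulates the experimental design the pipeline is built for: a venom split at a
~10 kDa cutoff, four proteolytic digests (trypsin 4 h partial, trypsin 18 h,
chymotrypsin 18 h, pepsin 18 h), and data-dependent acquisition in which each
selected precursor (MS1 window m/z 350-1,800) is fragmented by CID, HCD and
ETD in turn, with 60 s dynamic exclusion.  Every emitted spectrum triple is
recorded in a ground-truth table so downstream stages can be scored exactly.

The simulator is seeded and bit-reproducible.  A noiseless preset (detection
probability 1, no m/z jitter, no intensity noise, no noise peaks) produces
spectra whose peaks are exactly the theoretical ion ladders.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AMINO_ACIDS,
    ION_OFFSETS,
    ION_TERMINUS,
    PROTON,
    RESIDUE_MASS,
    WATER,
    peptide_mass,
    residue_sum,
)
from .model import Peak, ProteinRecord, Spectrum, SpectrumTriple, sorted_peak_arrays

MZ_MIN, MZ_MAX = 350.0, 1800.0
DYNAMIC_EXCLUSION_S = 60.0
TOP_N = 3


# ---------------------------------------------------------------------------
# Proteases and digestion


@dataclass(frozen=True)
class ProteaseRule:
    """C-terminal cleavage rule: cut after ``cleave_after`` unless the next
    residue is in ``not_before``."""

    name: str
    cleave_after: frozenset[str]
    not_before: frozenset[str] = frozenset()


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = ProteaseRule("chymotrypsin", frozenset("FWY"), frozenset("P"))
PEPSIN = ProteaseRule("pepsin", frozenset("FLWY"))  # pH-2 style specificity


@dataclass(frozen=True)
class DigestSpec:
    """One digest condition.

    ``p_cleave`` models digestion completeness in stochastic mode (a 4 h
    partial trypsin digest cuts fewer susceptible sites than an 18 h one);
    ``max_missed`` is used instead in deterministic mode (seed ``None``).
    """

    name: str
    rule: ProteaseRule
    p_cleave: float = 0.9
    max_missed: int = 1
    len_min: int = 4
    len_max: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cleave <= 1.0:
            raise ValueError("p_cleave must be in [0, 1]")
        if self.len_min < 4:
            raise ValueError("len_min must be at least 4")


def default_digests() -> list[DigestSpec]:
    """The study's four digest conditions.

    The only stated difference between the two trypsin digests is incubation
    time; partial digestion is modelled as a lower per-site cut probability
    (stochastic mode) or more missed cleavages (deterministic mode).
    """
    return [
        DigestSpec("trypsin_4h", TRYPSIN, p_cleave=0.5, max_missed=2),
        DigestSpec("trypsin_18h", TRYPSIN, p_cleave=0.9, max_missed=1),
        DigestSpec("chymotrypsin_18h", CHYMOTRYPSIN, p_cleave=0.9, max_missed=1),
        DigestSpec("pepsin_18h", PEPSIN, p_cleave=0.9, max_missed=1),
    ]


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """0-based positions i such that the bond after residue i is susceptible."""
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residue letters {sorted(bad)}")
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.not_before
    ]


def digest(
    sequence: str,
    spec: DigestSpec,
    rng: np.random.Generator | None = None,
    length_filter: bool = True,
) -> list[tuple[str, int]]:
    """Digest ``sequence``; returns (peptide, 0-based start) pairs.

    With ``rng`` given, each susceptible site is cut independently with
    probability ``p_cleave`` and the products are the resulting segments.
    Without ``rng`` (deterministic mode), all products with at most
    ``max_missed`` missed cleavages are enumerated.
    """
    sites = cleavage_sites(sequence, spec.rule)
    n = len(sequence)
    products: list[tuple[str, int]] = []
    if rng is not None:
        cut = [s for s in sites if rng.random() < spec.p_cleave]
        bounds = [0] + [s + 1 for s in cut] + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            products.append((sequence[a:b], a))
    else:
        bounds = [0] + [s + 1 for s in sites] + [n]
        for i, j in itertools.combinations(range(len(bounds)), 2):
            if j - i - 1 > spec.max_missed:
                continue
            a, b = bounds[i], bounds[j]
            products.append((sequence[a:b], a))
    if length_filter:
        products = [
            (p, a) for p, a in products if spec.len_min <= len(p) <= spec.len_max
        ]
    return products


# ---------------------------------------------------------------------------
# Proteome generation and fractionation


def generate_proteome(
    n: int,
    len_range: tuple[int, int] = (60, 200),
    seed: int | np.random.Generator = 0,
    frequencies: Mapping[str, float] | None = None,
    extra: Sequence[ProteinRecord] = (),
) -> list[ProteinRecord]:
    """Generate ``n`` random protein records.

    Residues are drawn i.i.d. from ``frequencies`` (uniform over the 20-letter
    alphabet by default); lengths are uniform over ``len_range`` inclusive.
    User-supplied records in ``extra`` are appended verbatim.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = len_range
    if lo < 4:
        raise ValueError("minimum protein length must be at least 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)
    if frequencies is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        probs = np.array([frequencies.get(a, 0.0) for a in letters], dtype=float)
        probs = probs / probs.sum()
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(
            ProteinRecord(
                accession=f"SYN{i + 1:04d}",
                description=f"synthetic venom protein {i + 1}",
                sequence=seq,
            )
        )
    return records + list(extra)


def protein_mass(record: ProteinRecord) -> float:
    """Monoisotopic residue-mass sum + water, the mass proxy for fractionation."""
    return residue_sum(record.sequence) + WATER


def fractionate(
    records: Sequence[ProteinRecord], cutoff_da: float = 10_000.0
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records at a molecular-weight cutoff: (above, below)."""
    if cutoff_da <= 0:
        raise ValueError("cutoff must be positive")
    above = [r for r in records if protein_mass(r) > cutoff_da]
    below = [r for r in records if protein_mass(r) <= cutoff_da]
    return above, below


# ---------------------------------------------------------------------------
# Fragmentation model


@dataclass(frozen=True)
class IonSeries:
    name: str                 # key into ION_OFFSETS / ION_TERMINUS
    p_detect: float = 0.95
    mean_intensity: float = 1.0

    @property
    def offset(self) -> float:
        return ION_OFFSETS[self.name]

    @property
    def terminus(self) -> str:
        return ION_TERMINUS[self.name]


@dataclass(frozen=True)
class ModeModel:
    series: tuple[IonSeries, ...]
    jitter_sd: float          # fragment m/z jitter s.d. (Da)
    noise_peaks: float        # Poisson mean of uniform noise peaks
    intensity_sd: float       # log-normal sigma of multiplicative intensity noise


@dataclass(frozen=True)
class FragmentationModel:
    """Per-mode ion series tables and noise levels.

    Defaults: CID b/y and ETD c/z read out in the ion trap (0.2 Da jitter),
    HCD b/y/a read out in the Orbitrap (0.01 Da jitter).
    """

    modes: Mapping[str, ModeModel] = field(
        default_factory=lambda: {
            "CID": ModeModel(
                (IonSeries("b", 0.95, 1.0), IonSeries("y", 0.95, 0.7)),
                jitter_sd=0.2, noise_peaks=20.0, intensity_sd=0.4,
            ),
            "HCD": ModeModel(
                (IonSeries("b", 0.9, 1.0), IonSeries("y", 0.9, 0.7),
                 IonSeries("a", 0.5, 0.3)),
                jitter_sd=0.01, noise_peaks=20.0, intensity_sd=0.4,
            ),
            "ETD": ModeModel(
                (IonSeries("c", 0.95, 1.0), IonSeries("z", 0.9, 0.8)),
                jitter_sd=0.2, noise_peaks=20.0, intensity_sd=0.4,
            ),
        }
    )

    def __post_init__(self) -> None:
        for mode, mm in self.modes.items():
            termini = {s.terminus for s in mm.series}
            if not {"N", "C"} <= termini:
                raise ValueError(
                    f"{mode}: each mode needs at least one N- and one C-terminal series"
                )
            for s in mm.series:
                if not 0.0 <= s.p_detect <= 1.0:
                    raise ValueError("detection probabilities must be in [0, 1]")

    def noiseless(self) -> "FragmentationModel":
        """Degenerate-noise preset: every ion detected, exact masses."""
        return FragmentationModel(
            {
                mode: ModeModel(
                    tuple(replace(s, p_detect=1.0) for s in mm.series),
                    jitter_sd=0.0, noise_peaks=0.0, intensity_sd=0.0,
                )
                for mode, mm in self.modes.items()
            }
        )


def theoretical_ions(
    peptide: str,
    mode: str,
    model: FragmentationModel | None = None,
    charge: int = 1,
) -> list[Peak]:
    """Theoretical singly protonated fragment ions of ``peptide`` for ``mode``.

    For each series and each cut site k (1..n-1): an N-terminal series carries
    the prefix residue-mass sum plus the series offset, a C-terminal series
    the suffix sum plus offset; m/z = neutral + proton.  Intensities are the
    series mean intensities.  ``charge`` refers to the precursor; fragments
    are modelled as 1+ throughout.
    """
    model = model or FragmentationModel()
    if mode not in model.modes:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(peptide)
    masses = np.array([RESIDUE_MASS[a] for a in peptide])
    prefix = np.cumsum(masses)
    total = prefix[-1] if n else 0.0
    peaks: list[Peak] = []
    for series in model.modes[mode].series:
        for k in range(1, n):
            frag = prefix[k - 1] if series.terminus == "N" else total - prefix[k - 1]
            peaks.append(Peak(frag + series.offset + PROTON, series.mean_intensity))
    peaks.sort()
    return peaks


def _precursor_mz(peptide: str, charge: int) -> float:
    return (peptide_mass(peptide) + charge * PROTON) / charge


def simulate_triple(
    peptide: str,
    charge: int,
    model: FragmentationModel,
    rng: np.random.Generator,
    triple_id: str = "",
    source_file: str = "synthetic.mgf",
    first_scan: int = 1,
    rt: float | None = None,
) -> SpectrumTriple:
    """Simulate the CID/HCD/ETD triple of one precursor."""
    if charge not in (2, 3):
        raise ValueError("precursor charge must be 2 or 3")
    pmz = _precursor_mz(peptide, charge)
    triple_id = triple_id or f"{peptide}/{charge}"
    spectra = {}
    for offset_scan, mode in enumerate(("CID", "HCD", "ETD")):
        mm = model.modes[mode]
        mz_list: list[float] = []
        int_list: list[float] = []
        n = len(peptide)
        masses = np.array([RESIDUE_MASS[a] for a in peptide])
        prefix = np.cumsum(masses)
        total = prefix[-1]
        for series in mm.series:
            for k in range(1, n):
                if rng.random() >= series.p_detect:
                    continue
                frag = prefix[k - 1] if series.terminus == "N" else total - prefix[k - 1]
                mz = frag + series.offset + PROTON
                if mm.jitter_sd > 0:
                    mz += rng.normal(0.0, mm.jitter_sd)
                inten = series.mean_intensity
                if mm.intensity_sd > 0:
                    inten *= float(np.exp(rng.normal(0.0, mm.intensity_sd)))
                mz_list.append(mz)
                int_list.append(inten)
        if mm.noise_peaks > 0:
            n_noise = int(rng.poisson(mm.noise_peaks))
            lo, hi = 100.0, max(200.0, pmz * charge)
            for _ in range(n_noise):
                mz_list.append(float(rng.uniform(lo, hi)))
                int_list.append(float(np.exp(rng.normal(np.log(0.05), 0.5))))
        mz_arr, int_arr = sorted_peak_arrays(list(zip(mz_list, int_list)))
        spectra[mode] = Spectrum(
            spectrum_id=f"{triple_id}.{mode}",
            source_file=source_file,
            scan=first_scan + offset_scan,
            precursor_mz=pmz,
            precursor_charge=charge,
            mode=mode,
            mz=mz_arr,
            intensity=int_arr,
            rt=rt,
        )
    return SpectrumTriple(
        cid=spectra["CID"], hcd=spectra["HCD"], etd=spectra["ETD"], triple_id=triple_id
    )


def eligible_charge(peptide: str) -> int | None:
    """Smallest charge in {2, 3} putting the precursor inside the MS1 window."""
    for z in (2, 3):
        if MZ_MIN <= _precursor_mz(peptide, z) <= MZ_MAX:
            return z
    return None


GROUND_TRUTH_COLUMNS = ["peptide", "accession", "start", "digest", "charge", "triple_id"]


def simulate_acquisition(
    pools: Mapping[str, Sequence[tuple[str, str, int, float]]],
    model: FragmentationModel,
    seed: int,
    dda: bool = False,
    gradient_s: float = 600.0,
    cycle_s: float = 5.0,
    elution_sd_s: float = 20.0,
) -> tuple[dict[str, list[SpectrumTriple]], pd.DataFrame]:
    """Acquire spectrum triples from per-digest peptide pools.

    ``pools`` maps digest name to (peptide, accession, start, abundance) rows.
    Precursors outside m/z 350-1,800 at both charge 2 and 3 are dropped.  With
    ``dda=False`` every eligible peptide yields exactly one triple.  With
    ``dda=True`` peptides elute as Gaussian profiles over a gradient; each
    ~5 s cycle selects the top-3 precursors by instantaneous abundance and
    places them on a 60 s exclusion list.
    """
    if not pools or any(len(v) == 0 for v in pools.values()):
        raise ValueError("peptide pools must be non-empty")
    rng = np.random.default_rng(seed)
    triples: dict[str, list[SpectrumTriple]] = {}
    gt_rows = []
    for digest_name in pools:
        pool = pools[digest_name]
        out: list[SpectrumTriple] = []
        scan = 1
        source = f"{digest_name}.mgf"

        def emit(peptide: str, accession: str, start: int, z: int, rt: float | None):
            nonlocal scan
            tid = f"{digest_name}:{len(out) + 1:05d}"
            out.append(
                simulate_triple(
                    peptide, z, model, rng,
                    triple_id=tid, source_file=source, first_scan=scan, rt=rt,
                )
            )
            gt_rows.append((peptide, accession, start, digest_name, z, tid))
            scan += 3

        if not dda:
            for peptide, accession, start, _abundance in pool:
                z = eligible_charge(peptide)
                if z is not None:
                    emit(peptide, accession, start, z, None)
        else:
            eligible = []
            for peptide, accession, start, abundance in pool:
                z = eligible_charge(peptide)
                if z is None:
                    continue
                rt_center = float(rng.uniform(0.0, gradient_s))
                eligible.append((peptide, accession, start, abundance, z, rt_center))
            excluded_until: dict[float, float] = {}
            t = 0.0
            while t <= gradient_s:
                candidates = []
                for peptide, accession, start, abundance, z, rt_c in eligible:
                    mz = _precursor_mz(peptide, z)
                    if excluded_until.get(round(mz, 3), -1.0) > t:
                        continue
                    inst = abundance * float(
                        np.exp(-0.5 * ((t - rt_c) / elution_sd_s) ** 2)
                    )
                    if inst > 1e-6:
                        candidates.append((inst, mz, peptide, accession, start, z))
                candidates.sort(key=lambda c: (-c[0], c[1]))
                for inst, mz, peptide, accession, start, z in candidates[:TOP_N]:
                    emit(peptide, accession, start, z, t)
                    excluded_until[round(mz, 3)] = t + DYNAMIC_EXCLUSION_S
                t += cycle_s
        triples[digest_name] = out
    ground_truth = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    return triples, ground_truth


def digest_pools(
    records: Sequence[ProteinRecord],
    digests: Sequence[DigestSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[str, str, int, float]]]:
    """Digest every record under every digest spec into acquisition pools.

    Abundances are 1.0 throughout (uniform); the acquisition simulator adds
    stochastic structure when DDA mode is on.
    """
    digests = list(digests) if digests is not None else default_digests()
    pools: dict[str, list[tuple[str, str, int, float]]] = {}
    for spec in digests:
        rows: list[tuple[str, str, int, float]] = []
        seen: set[tuple[str, str, int]] = set()
        for rec in records:
            for peptide, start in digest(rec.sequence, spec, rng):
                key = (peptide, rec.accession, start)
                if key in seen:
                    continue
                seen.add(key)
                rows.append((peptide, rec.accession, start, 1.0))
        pools[spec.name] = rows
    return pools
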