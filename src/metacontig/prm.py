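"""Prefix-residue-mass (PRM) transform and triple merging.

Every MS/MS peak is reinterpreted under each ion series of its fragmentation
mode as a putative cumulative N-terminal residue mass with a log-odds score,
and the three PRM spectra of a CID/HCD/ETD triple are merged into one spectrum
per precursor by adding the scores of matching masses.  Interpretations of b/y
(or c/z) ions from the same backbone cut corroborate the same PRM mass, which
is what makes the merged spectrum so much cleaner than any single scan.

Scoring is a rank-based log-odds: score = log(tier_likelihood(intensity rank)
* series_prior / noise_likelihood).  The default noise likelihood (0.05) keeps
all default log-odds positive, so that a PRM mass corroborated by all three
modes always outscores one explainable by at most two -- the property the
downstream assembly floor relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import ION_OFFSETS, ION_TERMINUS, MODES, PROTON
from .model import PRMSpectrum, Spectrum, SpectrumTriple

#: per-mode fragment tolerance defaults (Da): ion-trap CID/ETD vs Orbitrap HCD
DEFAULT_FRAG_TOL = {"CID": 0.4, "HCD": 0.02, "ETD": 0.4}
DEFAULT_MERGE_TOL = 0.3


@dataclass(frozen=True)
class ScoringModel:
    """Rank-tier likelihood model, one prior per ion series per mode."""

    priors: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CID": {"b": 0.4, "y": 0.4},
            "HCD": {"b": 0.35, "y": 0.35, "a": 0.1},
            "ETD": {"c": 0.45, "z": 0.45},
        }
    )
    #: (rank bound, likelihood ratio) tiers, highest intensity first
    tiers: tuple[tuple[int, float], ...] = ((10, 8.0), (25, 4.0), (50, 2.0))
    rest_likelihood: float = 1.0
    noise_likelihood: float = 0.05

    def __post_init__(self) -> None:
        ratios = [r for _, r in self.tiers] + [self.rest_likelihood]
        if any(r <= 0 for r in ratios) or self.noise_likelihood <= 0:
            raise ValueError("likelihood ratios must be positive")

    def tier_likelihood(self, rank: int) -> float:
        for bound, ratio in self.tiers:
            if rank <= bound:
                return ratio
        return self.rest_likelihood

    def score(self, rank: int, mode: str, series: str) -> float:
        return math.log(
            self.tier_likelihood(rank) * self.priors[mode][series] / self.noise_likelihood
        )


MODE_BITS = {"CID": 1, "HCD": 2, "ETD": 4}


def _merge_candidates(
    masses: np.ndarray, scores: np.ndarray, tol: float, reduce: str,
    modes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Single-linkage clustering along the mass axis (gap > tol splits).

    ``reduce`` is "max" (within one spectrum: co-incident interpretations are
    alternatives, keep the strongest) or "sum" (across the triple: matching
    masses corroborate each other, scores add; mass is the score-weighted
    mean).  Mode bitmasks, when given, are OR-ed within a cluster.
    """
    if masses.size == 0:
        return masses, scores, modes
    order = np.argsort(masses, kind="stable")
    masses, scores = masses[order], scores[order]
    if modes is not None:
        modes = modes[order]
    breaks = np.flatnonzero(np.diff(masses) > tol) + 1
    out_m, out_s, out_b = [], [], []
    segments = zip(
        np.split(masses, breaks),
        np.split(scores, breaks),
        np.split(modes, breaks) if modes is not None else np.split(masses, breaks),
    )
    for seg_m, seg_s, seg_b in segments:
        if reduce == "max":
            k = int(np.argmax(seg_s))
            out_m.append(seg_m[k])
            out_s.append(seg_s[k])
        else:
            w = np.clip(seg_s, 1e-9, None)  # weights must stay positive
            out_m.append(float(np.average(seg_m, weights=w)))
            out_s.append(float(seg_s.sum()))
        if modes is not None:
            out_b.append(np.bitwise_or.reduce(seg_b.astype(np.uint8)))
    return (
        np.asarray(out_m),
        np.asarray(out_s),
        np.asarray(out_b, dtype=np.uint8) if modes is not None else None,
    )


def spectrum_to_prm(
    s: Spectrum,
    model: ScoringModel | None = None,
    frag_tol: float | None = None,
) -> PRMSpectrum:
    """Convert one MS/MS scan into a scored PRM spectrum.

    All fragments are treated as singly protonated.  Both the N- and the
    C-terminal reading of every series-compatible peak are generated; the
    mirror ambiguity is resolved downstream by corroboration across the triple
    and the network.  Candidates outside (0, M) are discarded; candidates
    within ``frag_tol`` of each other collapse to the best-scoring one.
    """
    model = model or ScoringModel()
    if s.mode not in model.priors:
        raise ValueError(f"unknown fragmentation mode {s.mode!r}")
    tol = DEFAULT_FRAG_TOL[s.mode] if frag_tol is None else frag_tol
    M = s.residue_mass_total
    n = len(s)
    cand_masses: list[float] = []
    cand_scores: list[float] = []
    if n:
        # intensity rank: 1 = most intense; ties broken toward lower m/z
        order = np.lexsort((s.mz, -s.intensity))
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(1, n + 1)
        for series in model.priors[s.mode]:
            offset = ION_OFFSETS[series]
            neutral = s.mz - PROTON - offset
            prm = neutral if ION_TERMINUS[series] == "N" else M - neutral
            ok = (prm > tol) & (prm < M - tol)
            for i in np.flatnonzero(ok):
                cand_masses.append(float(prm[i]))
                cand_scores.append(model.score(int(rank[i]), s.mode, series))
    masses, scores, _ = _merge_candidates(
        np.asarray(cand_masses), np.asarray(cand_scores), tol, "max"
    )
    return PRMSpectrum(
        spectrum_id=s.spectrum_id, M=M, masses=masses, scores=scores,
        provenance=(s.mode,),
        peak_modes=np.full(masses.size, MODE_BITS[s.mode], dtype=np.uint8),
    )


def merge_triple(
    prms: Sequence[PRMSpectrum],
    merge_tol: float = DEFAULT_MERGE_TOL,
    precursor_tol: float = 0.05,
    merged_id: str | None = None,
) -> PRMSpectrum:
    """Merge the three per-mode PRM spectra of one precursor.

    Peaks are clustered by single linkage along the mass axis (a gap larger
    than ``merge_tol`` splits clusters); each cluster becomes one peak at the
    score-weighted mean mass with the SUM of member scores, so total score is
    conserved.  The merge is permutation-invariant in its inputs.
    """
    if not prms:
        raise ValueError("nothing to merge")
    Ms = [p.M for p in prms]
    if max(Ms) - min(Ms) > precursor_tol:
        raise ValueError(
            f"precursor mass mismatch across the triple: {max(Ms) - min(Ms):.4f} Da"
        )
    masses = np.concatenate([p.masses for p in prms]) if prms else np.empty(0)
    scores = np.concatenate([p.scores for p in prms])
    bits = np.concatenate(
        [
            p.peak_modes
            if p.peak_modes is not None
            else np.full(len(p), sum(MODE_BITS[m] for m in p.provenance), dtype=np.uint8)
            for p in prms
        ]
    ).astype(np.uint8)
    out_m, out_s, out_b = _merge_candidates(masses, scores, merge_tol, "sum", bits)
    provenance = tuple(
        m for m in MODES if any(m in p.provenance and len(p) for p in prms)
    )
    return PRMSpectrum(
        spectrum_id=merged_id or prms[0].spectrum_id.rsplit(".", 1)[0],
        M=float(np.mean(Ms)),
        masses=out_m,
        scores=out_s,
        provenance=provenance,
        peak_modes=out_b,
    )


def triple_to_prm(
    triple: SpectrumTriple,
    model: ScoringModel | None = None,
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> PRMSpectrum:
    """Full PRM conversion of one spectrum triple (convert each scan, merge)."""
    parts = [spectrum_to_prm(s, model) for s in triple.spectra]
    return merge_triple(parts, merge_tol=merge_tol, merged_id=triple.triple_id)
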