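"""Spectral networks: shifted pairwise alignment of merged PRM spectra.

Two peptides with overlapping sequences (different proteases, missed
cleavages) produce PRM spectra whose peaks match after shifting one spectrum
by the mass of the unshared prefix.  ``align_pair`` searches all candidate
shifts (pairwise mass differences, with the boundary masses 0 and M included
virtually) and, per shift, finds the optimal monotone matching by dynamic
programming.  ``build_network`` applies this all-versus-all and keeps edges
passing the match-count and score thresholds; the score threshold defaults to
a decoy-calibrated value (twice the mean score of shuffled-mass alignments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import PRMSpectrum

log = logging.getLogger(__name__)

DEFAULT_ALIGN_TOL = 0.3
DEFAULT_MIN_MATCHES = 5


@dataclass
class PairwiseAlignment:
    """A shifted peak matching between two PRM spectra.

    ``shift`` is the mass of the prefix by which ``b`` is offset inside
    ``a``'s coordinate frame (may be negative): matched pairs satisfy
    ``|mass_a - (mass_b + shift)| <= align_tol``.  ``matched_pairs`` indexes
    real peaks only (the virtual boundaries anchor shifts but are not
    counted); indices are strictly increasing in both coordinates.
    """

    id_a: str
    id_b: str
    shift: float
    matched_pairs: list[tuple[int, int]]
    score: float
    offset_shift: float | None = None  # second-segment shift when a PTM offset was allowed

    @property
    def n_matches(self) -> int:
        return len(self.matched_pairs)

    def reversed(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            id_a=self.id_b,
            id_b=self.id_a,
            shift=-self.shift,
            matched_pairs=[(j, i) for i, j in self.matched_pairs],
            score=self.score,
            offset_shift=-self.offset_shift if self.offset_shift is not None else None,
        )


def _augmented(p: PRMSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Masses/scores with the virtual boundary peaks 0 and M (score 0)."""
    m = np.concatenate(([0.0], p.masses, [p.M]))
    s = np.concatenate(([0.0], p.scores, [0.0]))
    return m, s


def _best_matching(
    am: np.ndarray, asc: np.ndarray, bm: np.ndarray, bsc: np.ndarray,
    shift: float, tol: float,
) -> tuple[float, list[tuple[int, int]]]:
    """Optimal monotone matching at a fixed shift.

    Feasible pairs are those with |am_i - bm_j - shift| <= tol; the matching
    must be strictly increasing in both indices.  Weighted-LIS dynamic
    programming maximises the summed pair scores (score_a + score_b; virtual
    boundary peaks carry 0).  Returns (score, matched index pairs including
    virtual ones).
    """
    diffs = am[:, None] - bm[None, :] - shift
    ii, jj = np.nonzero(np.abs(diffs) <= tol)
    if ii.size == 0:
        return 0.0, []
    order = np.lexsort((jj, ii))
    ii, jj = ii[order], jj[order]
    w = asc[ii] + bsc[jj]
    k = ii.size
    dp = w.copy()
    parent = np.full(k, -1, dtype=int)
    for p in range(k):
        best = 0.0
        arg = -1
        for q in range(p):
            if ii[q] < ii[p] and jj[q] < jj[p] and dp[q] > best:
                best = dp[q]
                arg = q
        dp[p] = w[p] + best
        parent[p] = arg
    end = int(np.argmax(dp))
    pairs: list[tuple[int, int]] = []
    p = end
    while p >= 0:
        pairs.append((int(ii[p]), int(jj[p])))
        p = parent[p]
    pairs.reverse()
    return float(dp[end]), pairs


def _candidate_shifts(
    am: np.ndarray, bm: np.ndarray, n_real_a: int, n_real_b: int,
    tol: float, min_matches: int,
) -> np.ndarray:
    """Candidate shifts: all pairwise differences whose +/-tol neighbourhood
    contains at least ``min_matches`` real-real differences."""
    all_diffs = (am[:, None] - bm[None, :]).ravel()
    real_diffs = np.sort(
        (am[1 : n_real_a + 1, None] - bm[None, 1 : n_real_b + 1]).ravel()
    )
    lo = np.searchsorted(real_diffs, all_diffs - tol, side="left")
    hi = np.searchsorted(real_diffs, all_diffs + tol, side="right")
    cands = np.sort(all_diffs[(hi - lo) >= min_matches])
    if cands.size == 0:
        return cands
    # dedupe numerically identical candidates
    keep = np.concatenate(([True], np.diff(cands) > 1e-9))
    return cands[keep]


def _window_consistent(
    a: PRMSpectrum, b: PRMSpectrum, shift: float, n_matched: int,
    tol: float, min_frac: float,
) -> bool:
    """True when the matching covers most ladder peaks in the overlap window.

    A genuine overlap alignment of two PRM ladders matches essentially every
    peak both spectra carry inside the overlap region, whereas a spurious
    shift (easy to find by chance, since PRM masses live on the residue-mass
    lattice) matches a scattered subset.  Requires the matched count to be at
    least ``min_frac`` of each spectrum's peak count inside the window.
    """
    if min_frac <= 0:
        return True
    lo_a, hi_a = max(0.0, shift) + tol, min(a.M, shift + b.M) - tol
    if hi_a <= lo_a:
        return False
    count_a = int(np.searchsorted(a.masses, hi_a) - np.searchsorted(a.masses, lo_a))
    lo_b, hi_b = lo_a - shift, hi_a - shift
    count_b = int(np.searchsorted(b.masses, hi_b) - np.searchsorted(b.masses, lo_b))
    need = min_frac * max(count_a, count_b)
    return n_matched >= need


def align_pair(
    a: PRMSpectrum,
    b: PRMSpectrum,
    align_tol: float = DEFAULT_ALIGN_TOL,
    min_matches: int = DEFAULT_MIN_MATCHES,
    allow_offset: bool = False,
    min_window_frac: float = 0.0,
    shift_coherence: float | None = None,
) -> PairwiseAlignment | None:
    """Best shifted alignment of two merged PRM spectra, or None.

    Every pairwise mass difference (boundaries included) is a candidate shift;
    the best-scoring one whose matching covers at least ``min_matches`` real
    peak pairs wins.  ``min_window_frac`` > 0 additionally requires each
    candidate's matching to cover that fraction of the peaks inside the
    overlap window (spurious-shift suppression; the network builder uses
    0.8).  With ``allow_offset`` the search additionally considers alignments
    with one internal offset change (two shifts), which is how an
    unanticipated modification between the two peptides shows up; such edges
    are annotated but not used by assembly.
    """
    am, asc = _augmented(a)
    bm, bsc = _augmented(b)
    na, nb = len(a), len(b)
    cands = _candidate_shifts(am, bm, na, nb, align_tol, max(min_matches, 1))
    best: tuple[float, int, float] | None = None
    best_result: PairwiseAlignment | None = None
    for shift in cands:
        score, pairs = _best_matching(am, asc, bm, bsc, float(shift), align_tol)
        real = [(i - 1, j - 1) for i, j in pairs if 1 <= i <= na and 1 <= j <= nb]
        if len(real) < min_matches:
            continue
        # re-centre the shift on the matched real pairs; a genuine overlap has
        # tightly coherent per-pair shifts, a lattice coincidence does not
        drift = [float(am[i + 1] - bm[j + 1]) for i, j in real]
        centred = float(np.median(drift))
        keep_tol = align_tol if shift_coherence is None else shift_coherence
        real = [
            (i, j) for (i, j), d in zip(real, drift) if abs(d - centred) <= keep_tol
        ]
        if len(real) < min_matches:
            continue
        centred = float(
            np.mean([am[i + 1] - bm[j + 1] for i, j in real])
        )
        if not _window_consistent(a, b, centred, len(real), align_tol, min_window_frac):
            continue
        score = float(sum(a.scores[i] + b.scores[j] for i, j in real))
        key = (score, len(real), -abs(centred))
        if best is None or key > best:
            best = key
            best_result = PairwiseAlignment(
                id_a=a.spectrum_id, id_b=b.spectrum_id, shift=centred,
                matched_pairs=real, score=score,
            )
    if allow_offset:
        two = _align_two_segment(a, b, am, asc, bm, bsc, align_tol, min_matches)
        if two is not None and (best is None or (two.score, two.n_matches) > (best[0], best[1])):
            best_result = two
    return best_result


def _align_two_segment(
    a: PRMSpectrum, b: PRMSpectrum,
    am: np.ndarray, asc: np.ndarray, bm: np.ndarray, bsc: np.ndarray,
    tol: float, min_matches: int, top_k: int = 6,
) -> PairwiseAlignment | None:
    """Best alignment with a single internal offset change (two shifts)."""
    na, nb = len(a), len(b)
    cands = _candidate_shifts(am, bm, na, nb, tol, 2)
    if cands.size < 2:
        return None
    scored = []
    for shift in cands:
        s, pairs = _best_matching(am, asc, bm, bsc, float(shift), tol)
        scored.append((s, float(shift), pairs))
    scored.sort(key=lambda t: -t[0])
    scored = scored[:top_k]
    best: PairwiseAlignment | None = None
    for s1, d1, p1 in scored:
        for s2, d2, p2 in scored:
            if abs(d1 - d2) <= tol:
                continue
            # combine: a prefix matched at d1, a suffix at d2, jointly monotone
            for cut_a in {i for i, _ in p1} | {0}:
                left = [(i, j) for i, j in p1 if i <= cut_a]
                jmax = max((j for _, j in left), default=-1)
                right = [(i, j) for i, j in p2 if i > cut_a and j > jmax]
                pairs = left + right
                real = [
                    (i - 1, j - 1) for i, j in pairs if 1 <= i <= na and 1 <= j <= nb
                ]
                if len(real) < min_matches or not right or not left:
                    continue
                score = float(sum(a.scores[i] + b.scores[j] for i, j in real))
                if best is None or score > best.score:
                    best = PairwiseAlignment(
                        id_a=a.spectrum_id, id_b=b.spectrum_id, shift=d1,
                        matched_pairs=real, score=score, offset_shift=d2,
                    )
    return best


def filter_peaks(
    p: PRMSpectrum, score_floor: float = 0.0, min_modes: int = 0
) -> PRMSpectrum:
    """Copy of ``p`` keeping confidently corroborated peaks.

    ``score_floor`` cuts on the summed log-odds; ``min_modes`` requires the
    peak to carry contributions from that many fragmentation modes (a true
    prefix mass is corroborated by CID, HCD and ETD ions of the same backbone
    cut, whereas b/y mirror masses never receive ETD support).
    """
    keep = p.scores >= score_floor
    if min_modes > 0 and p.peak_modes is not None:
        popcount = np.array([bin(int(b)).count("1") for b in p.peak_modes])
        keep &= popcount >= min_modes
    return PRMSpectrum(
        spectrum_id=p.spectrum_id, M=p.M,
        masses=p.masses[keep], scores=p.scores[keep], provenance=p.provenance,
        peak_modes=p.peak_modes[keep] if p.peak_modes is not None else None,
    )


def calibrate_min_score(
    prms: list[PRMSpectrum],
    align_tol: float,
    min_matches: int,
    rng: np.random.Generator,
    n_decoy: int = 40,
) -> float:
    """Decoy-based score threshold: 2x the mean score of alignments between
    shuffled-mass versions of random spectrum pairs (0 when decoys never
    align, which is the common case at realistic ``min_matches``)."""
    usable = [p for p in prms if len(p) >= min_matches]
    if len(usable) < 2:
        return 0.0
    scores = []
    for _ in range(n_decoy):
        pa, pb = rng.choice(len(usable), size=2, replace=False)
        decoys = []
        for p in (usable[pa], usable[pb]):
            masses = np.sort(rng.uniform(0.5, p.M - 0.5, size=len(p)))
            masses = masses[np.concatenate(([True], np.diff(masses) > 1e-6))]
            decoys.append(
                PRMSpectrum(
                    spectrum_id=p.spectrum_id, M=p.M,
                    masses=masses, scores=p.scores[: masses.size],
                    provenance=p.provenance,
                )
            )
        al = align_pair(decoys[0], decoys[1], align_tol, min_matches)
        scores.append(al.score if al is not None else 0.0)
    return 2.0 * float(np.mean(scores))


DEFAULT_MIN_WINDOW_FRAC = 0.8
DEFAULT_SHIFT_COHERENCE = 0.2


#: all-versus-all search multiplies the chance of lattice coincidences, so the
#: network edge threshold is stricter than a single pairwise comparison: seven
#: matched pairs require a shared ladder of at least six residues
DEFAULT_NETWORK_MIN_MATCHES = 7


def build_network(
    prms: list[PRMSpectrum],
    align_tol: float = DEFAULT_ALIGN_TOL,
    min_matches: int = DEFAULT_NETWORK_MIN_MATCHES,
    min_score: float | None = None,
    peak_score_floor: float | None = None,
    min_modes: int = 3,
    min_window_frac: float = DEFAULT_MIN_WINDOW_FRAC,
    shift_coherence: float | None = DEFAULT_SHIFT_COHERENCE,
    seed: int = 0,
) -> nx.Graph:
    """All-versus-all alignment into an undirected spectral network.

    Nodes are spectrum ids (isolated nodes allowed); an edge is kept iff its
    alignment has at least ``min_matches`` matched pairs and a score at or
    above ``min_score`` (decoy-calibrated when None).  ``peak_score_floor``
    optionally restricts alignment to confidently corroborated PRM masses.
    """
    ids = [p.spectrum_id for p in prms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate PRM spectrum ids")
    if peak_score_floor is not None or min_modes > 0:
        prms = [
            filter_peaks(p, peak_score_floor or 0.0, min_modes) for p in prms
        ]
    if min_score is None:
        rng = np.random.default_rng(seed)
        min_score = calibrate_min_score(prms, align_tol, min_matches, rng)
        log.info("decoy-calibrated min_score = %.2f", min_score)
    g = nx.Graph()
    for p in prms:
        g.add_node(p.spectrum_id, prm=p)
    nonempty = [p for p in prms if len(p) >= min_matches]
    for i in range(len(nonempty)):
        for j in range(i + 1, len(nonempty)):
            al = align_pair(
                nonempty[i], nonempty[j], align_tol, min_matches,
                min_window_frac=min_window_frac, shift_coherence=shift_coherence,
            )
            if al is not None and al.score >= min_score:
                g.add_edge(al.id_a, al.id_b, alignment=al)
    return g
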