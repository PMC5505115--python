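"""Gap-tolerant mapping of de novo sequences onto a protein database.

A gapped de novo sequence is placed on a protein by dynamic programming: a
residue element must match an identical protein residue (I and L are
equivalent), a gap element consumes any stretch of 1..max_gap_residues
protein residues whose summed residue mass is within ``gap_tol`` of the gap
mass, and no other insertions or deletions are allowed.  Matches are scored
by the number of matched residue elements.  The mapped set is reduced to a
minimal protein list by greedy set cover (maximum parsimony), after removing
contaminants and the sample-preparation proteases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import RESIDUE_MASS
from .denovo import DeNovoSequence
from .model import ProteinRecord

DEFAULT_GAP_TOL = 0.05
DEFAULT_MIN_MATCHED = 6
DEFAULT_MAX_GAP_RESIDUES = 6


@dataclass
class HomologyMatch:
    contig_id: str
    accession: str
    start: int                       # 0-based, half-open protein coordinates
    end: int
    matched_residues: int
    gap_spans: list[tuple[int, tuple[int, int]]]  # (element index, consumed range)
    score: float
    best: bool = False


@dataclass
class ParsimonyReport:
    selected: list[str]
    support: dict[str, list[str]]    # accession -> supporting contig ids
    excluded_contaminants: list[str] = field(default_factory=list)


def _equiv(a: str, b: str) -> bool:
    return a == b or {a, b} == {"I", "L"}


def align_denovo_to_protein(
    seq: DeNovoSequence,
    protein: ProteinRecord,
    gap_tol: float = DEFAULT_GAP_TOL,
    min_matched: int = DEFAULT_MIN_MATCHED,
    max_gap_residues: int = DEFAULT_MAX_GAP_RESIDUES,
) -> HomologyMatch | None:
    """Best placement of the whole gapped sequence on one protein, or None.

    All elements must be consumed; among equally scoring placements the one
    with the smallest start (then end) position is returned.
    """
    p = protein.sequence
    L = len(p)
    if not seq.elements:
        return None
    prefix = np.zeros(L + 1)
    for i, a in enumerate(p):
        prefix[i + 1] = prefix[i] + RESIDUE_MASS[a]
    # frontier: position -> (previous position, consumed range for gaps)
    frontier: dict[int, tuple[int, tuple[int, int] | None]] = {
        pos: (-1, None) for pos in range(L)
    }
    trace: list[dict[int, tuple[int, tuple[int, int] | None]]] = [dict(frontier)]
    for e in seq.elements:
        nxt: dict[int, tuple[int, tuple[int, int] | None]] = {}
        if e.kind == "residue":
            for pos in frontier:
                if pos < L and _equiv(p[pos], e.letter):
                    prev = nxt.get(pos + 1)
                    if prev is None or pos < prev[0]:
                        nxt[pos + 1] = (pos, None)
        else:
            for pos in frontier:
                for k in range(1, max_gap_residues + 1):
                    if pos + k > L:
                        break
                    span_mass = prefix[pos + k] - prefix[pos]
                    if span_mass > e.mass + gap_tol:
                        break
                    if abs(span_mass - e.mass) <= gap_tol:
                        prev = nxt.get(pos + k)
                        if prev is None or pos < prev[0]:
                            nxt[pos + k] = (pos, (pos, pos + k))
        if not nxt:
            return None
        frontier = nxt
        trace.append(dict(frontier))
    matched = seq.n_residues
    if matched < min_matched:
        return None
    # reconstruct the placement ending earliest-start (trace back each end)
    best_placement: tuple[int, int, list] | None = None
    for end in sorted(frontier):
        pos = end
        spans: list[tuple[int, tuple[int, int]]] = []
        ok = True
        for ei in range(len(seq.elements), 0, -1):
            entry = trace[ei].get(pos)
            if entry is None:
                ok = False
                break
            prev, span = entry
            if span is not None:
                spans.append((ei - 1, span))
            pos = prev
        if not ok:
            continue
        spans.reverse()
        cand = (pos, end, spans)
        if best_placement is None or (cand[0], cand[1]) < (best_placement[0], best_placement[1]):
            best_placement = cand
    if best_placement is None:
        return None
    start, end, spans = best_placement
    return HomologyMatch(
        contig_id=seq.contig_id,
        accession=protein.accession,
        start=start,
        end=end,
        matched_residues=matched,
        gap_spans=spans,
        score=float(matched),
    )


def search_database(
    seqs: list[DeNovoSequence],
    db: list[ProteinRecord],
    gap_tol: float = DEFAULT_GAP_TOL,
    min_matched: int = DEFAULT_MIN_MATCHED,
    max_gap_residues: int = DEFAULT_MAX_GAP_RESIDUES,
) -> list[HomologyMatch]:
    """All (sequence, protein) pairs; every match retained, best one flagged.

    Deterministic ordering: per sequence by score descending then accession
    ascending; the first match per sequence carries the ``best`` flag.
    """
    if not db:
        raise ValueError("empty protein database")
    matches: list[HomologyMatch] = []
    for seq in seqs:
        hits = []
        for protein in db:
            m = align_denovo_to_protein(seq, protein, gap_tol, min_matched, max_gap_residues)
            if m is not None:
                hits.append(m)
        hits.sort(key=lambda m: (-m.score, m.accession))
        if hits:
            hits[0].best = True
        matches.extend(hits)
    return matches


def bundled_contaminants() -> set[str]:
    text = (
        resources.files("metacontig.data")
        .joinpath("contaminant_accessions.txt")
        .read_text()
    )
    return {
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def filter_contaminants(
    matches: list[HomologyMatch],
    contaminant_accessions: set[str] | None = None,
) -> tuple[list[HomologyMatch], list[HomologyMatch]]:
    """Split matches into (kept, removed-as-contaminant)."""
    if contaminant_accessions is None:
        contaminant_accessions = bundled_contaminants()
    kept = [m for m in matches if m.accession not in contaminant_accessions]
    removed = [m for m in matches if m.accession in contaminant_accessions]
    return kept, removed


def parsimony_group(matches: list[HomologyMatch]) -> ParsimonyReport:
    """Greedy minimum set cover of contigs by accessions.

    Repeatedly select the accession covering the most not-yet-covered
    contigs; ties go to the accession with more total matches, then to the
    lexicographically smaller accession.
    """
    if not matches:
        raise ValueError("no matches to group")
    contigs_of: dict[str, set[str]] = {}
    total_matches: dict[str, int] = {}
    for m in matches:
        contigs_of.setdefault(m.accession, set()).add(m.contig_id)
        total_matches[m.accession] = total_matches.get(m.accession, 0) + 1
    uncovered = {m.contig_id for m in matches}
    selected: list[str] = []
    support: dict[str, list[str]] = {}
    while uncovered:
        acc = max(
            contigs_of,
            key=lambda a: (
                len(contigs_of[a] & uncovered),
                total_matches[a],
                [-ord(c) for c in a],
            ),
        )
        gain = contigs_of[acc] & uncovered
        if not gain:
            break
        selected.append(acc)
        support[acc] = sorted(contigs_of[acc])
        uncovered -= gain
    return ParsimonyReport(selected=sorted(selected), support=support)
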