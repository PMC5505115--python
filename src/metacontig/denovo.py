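"""Gapped de novo sequences from consensus PRM spectra.

A meta-contig's consensus masses are read out as a string of residue letters
(where adjacent masses differ by exactly one residue mass) and bracketed gap
masses (where zero or two-plus residues would fit), e.g.
``GVIIHE[291.835][227.31]GFY``.  Isoleucine and leucine are isobaric; a
residue-mass difference of 113.08406 is reported as 'I' and the I/L
equivalence is handled again by the homology mapper.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .constants import RESIDUE_MASS

#: residue lookup used for calling; L is folded into I (isobaric)
CALL_TABLE: dict[str, float] = {
    a: m for a, m in sorted(RESIDUE_MASS.items()) if a != "L"
}

DEFAULT_CALL_TOL = 0.02


@dataclass(frozen=True)
class DeNovoElement:
    kind: str                     # "residue" or "gap"
    mass: float
    letter: str = ""              # residue only
    raw: str = ""                 # printed digits of a parsed gap, kept verbatim

    def __post_init__(self) -> None:
        if self.kind not in ("residue", "gap"):
            raise ValueError(f"bad element kind {self.kind!r}")
        if self.kind == "residue" and self.letter not in RESIDUE_MASS:
            raise ValueError(f"bad residue letter {self.letter!r}")
        if self.mass <= 0:
            raise ValueError("element mass must be positive")


def residue_element(letter: str) -> DeNovoElement:
    return DeNovoElement(kind="residue", mass=RESIDUE_MASS[letter], letter=letter)


def gap_element(mass: float, raw: str = "") -> DeNovoElement:
    return DeNovoElement(kind="gap", mass=mass, raw=raw)


@dataclass
class DeNovoSequence:
    contig_id: str
    elements: list[DeNovoElement]
    confidences: list[float] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(1 for e in self.elements if e.kind == "residue")

    @property
    def n_gaps(self) -> int:
        return sum(1 for e in self.elements if e.kind == "gap")

    @property
    def total_mass(self) -> float:
        return sum(e.mass for e in self.elements)

    def __str__(self) -> str:
        return format_denovo_string(self)


def _call_delta(delta: float, call_tol: float) -> str | None:
    """Letter if exactly one residue mass fits ``delta``, else None."""
    hits = {
        round(m, 5): a for a, m in CALL_TABLE.items() if abs(delta - m) <= call_tol
    }
    if len(hits) == 1:
        return next(iter(hits.values()))
    return None


def sequence_consensus(
    mc,
    call_tol: float = DEFAULT_CALL_TOL,
    contig_id: str | None = None,
) -> DeNovoSequence:
    """Read a meta-contig's consensus spectrum as a gapped de novo sequence.

    The boundary masses 0 and the span M are prepended/appended; every
    adjacent mass difference becomes either a residue element (exactly one
    residue mass within ``call_tol``) or a gap element of that mass.  Each
    element's confidence is the smaller consensus score of its two bounding
    masses (boundaries count as fully supported).
    """
    masses = [0.0] + [float(m) for m in mc.masses] + [float(mc.span)]
    scores = [float("inf")] + [float(s) for s in mc.scores] + [float("inf")]
    for a, b in zip(masses[:-1], masses[1:]):
        if b <= a:
            raise ValueError("consensus masses must be strictly increasing")
    elements: list[DeNovoElement] = []
    confidences: list[float] = []
    for i in range(len(masses) - 1):
        delta = masses[i + 1] - masses[i]
        letter = _call_delta(delta, call_tol)
        if letter is not None:
            elements.append(residue_element(letter))
        else:
            elements.append(gap_element(delta))
        conf = min(scores[i], scores[i + 1])
        confidences.append(conf if conf != float("inf") else max(scores[1:-1], default=0.0))
    return DeNovoSequence(
        contig_id=contig_id or getattr(mc, "contig_id", ""),
        elements=elements,
        confidences=confidences,
    )


_TOKEN_RE = re.compile(r"([ACDEFGHIKLMNPQRSTVWY])|\[(\d+(?:\.\d{1,6})?)\]")


class DeNovoParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def parse_denovo_string(s: str, contig_id: str = "") -> DeNovoSequence:
    """Parse a gapped de novo string such as ``[168.09]PDATIVY[128.106]``.

    Residue letters come from the 20-letter alphabet; bracketed decimal
    masses are gaps, their printed digits kept verbatim.  Anything else —
    including an empty string — is a parse error carrying the position.
    """
    if not s:
        raise DeNovoParseError("empty de novo string", 0)
    elements: list[DeNovoElement] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            what = "unbalanced bracket or bad gap mass" if s[pos] == "[" else (
                f"illegal residue letter {s[pos]!r}"
            )
            raise DeNovoParseError(what, pos)
        if m.group(1):
            elements.append(residue_element(m.group(1)))
        else:
            elements.append(gap_element(float(m.group(2)), raw=m.group(2)))
        pos = m.end()
    return DeNovoSequence(contig_id=contig_id, elements=elements)


def _format_gap_mass(mass: float) -> str:
    text = f"{mass:.3f}".rstrip("0").rstrip(".")
    return text or "0"


def format_denovo_string(seq: DeNovoSequence) -> str:
    """Inverse of :func:`parse_denovo_string`.

    Residues print as letters; gaps as ``[m]`` with m to 3 decimals, trailing
    zeros trimmed — except that gaps parsed from text keep their printed
    digits verbatim, so format(parse(s)) == s.
    """
    out = []
    for e in seq.elements:
        if e.kind == "residue":
            out.append(e.letter)
        else:
            out.append(f"[{e.raw or _format_gap_mass(e.mass)}]")
    return "".join(out)


def gap_compositions(
    mass: float, tol: float = 0.01, max_residues: int = 6
) -> set[tuple[str, ...]]:
    """All multisets of at most ``max_residues`` residues summing to ``mass``.

    Bounded depth-first enumeration over non-decreasing residue masses; I/L
    are reported as 'I'.  Returns sorted letter tuples.
    """
    if mass <= 0:
        raise ValueError("gap mass must be positive")
    items = sorted(CALL_TABLE.items(), key=lambda kv: kv[1])
    out: set[tuple[str, ...]] = set()

    def extend(start: int, remaining: float, depth: int, acc: list[str]) -> None:
        if abs(remaining) <= tol and acc:
            out.add(tuple(sorted(acc)))
        if depth == max_residues:
            return
        for k in range(start, len(items)):
            letter, m = items[k]
            if m > remaining + tol:
                break
            acc.append(letter)
            extend(k, remaining - m, depth + 1, acc)
            acc.pop()

    extend(0, mass, 0, [])
    return out


def load_reference_corpus() -> list[str]:
    """Bundled corpus of gapped de novo strings from published spider-venom
    meta-contig assemblies; used as a notation-fidelity fixture."""
    text = (
        resources.files("metacontig.data")
        .joinpath("gapped_denovo_corpus.txt")
        .read_text()
    )
    return [line for line in text.splitlines() if line.strip()]
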