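"""Readers and writers for the formats the pipeline touches.

MGF (Mascot generic format) is the sole spectral input dialect.  The
fragmentation mode of each scan is carried in a non-standard ``FRAGMODE=``
header line (a ``mode=<MODE>`` token inside TITLE is also understood); MGF has
no standard key for it and explicit beats inference.  FASTA goes through
Biopython; every tabular artifact is UTF-8 TSV.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .constants import AMINO_ACIDS
from .model import PRMSpectrum, ProteinRecord, Spectrum, SpectrumTriple, sorted_peak_arrays

log = logging.getLogger(__name__)

_TITLE_MODE_RE = re.compile(r"\bmode=(CID|HCD|ETD)\b", re.IGNORECASE)


def read_mgf(path: str | Path, default_mode: str | None = None) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects, in file order.

    Blocks without PEPMASS are rejected and logged.  CHARGE defaults to 2+
    when absent (data-dependent acquisition of mostly 2-3+ species).  A block
    with no recognisable fragmentation mode and no ``default_mode`` is a hard
    error naming the block.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for ordinal, entry in enumerate(_mgf.read(fh, use_index=False), start=1):
            params = entry["params"]
            title = str(params.get("title", "")).strip()
            spectrum_id = title or f"{path.name}:{ordinal}"
            if spectrum_id in seen_ids:
                spectrum_id = f"{spectrum_id}#{ordinal}"
            seen_ids.add(spectrum_id)
            if "pepmass" not in params:
                log.warning("%s: block %r has no PEPMASS; rejected", path.name, spectrum_id)
                continue
            pepmass = params["pepmass"]
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge_val = params.get("charge")
            if charge_val:
                charge = int(charge_val[0])
            else:
                charge = 2
                log.debug("%s: block %r has no CHARGE; assuming 2+", path.name, spectrum_id)
            mode = str(params.get("fragmode", "")).upper() or None
            if mode is None:
                m = _TITLE_MODE_RE.search(title)
                mode = m.group(1).upper() if m else None
            if mode is None:
                mode = default_mode
            if mode is None:
                raise ValueError(
                    f"{path.name}: block {spectrum_id!r} carries no FRAGMODE/mode "
                    "token and no default_mode was given"
                )
            scan_raw = str(params.get("scans", "")).strip()
            scan = int(scan_raw) if scan_raw.isdigit() else ordinal
            rt = params.get("rtinseconds")
            mz, inten = sorted_peak_arrays(
                list(zip(entry["m/z array"], entry["intensity array"]))
            )
            spectra.append(
                Spectrum(
                    spectrum_id=spectrum_id,
                    source_file=path.name,
                    scan=scan,
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    mode=mode.upper(),
                    mz=mz,
                    intensity=inten,
                    rt=float(rt) if rt is not None else None,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> Path:
    """Write spectra to MGF; m/z printed to 5 decimals, intensity to 3."""
    path = Path(path)
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": s.precursor_charge,
            "scans": s.scan,
            "fragmode": s.mode,
        }
        if s.rt is not None:
            params["rtinseconds"] = s.rt
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with path.open("w") as fh:
        _mgf.write(entries, fh, fragment_format="{:.5f} {:.3f}")
    return path


_HEADER_RE = re.compile(r"^(\S+)\s*(.*)$")


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], int]:
    """Read FASTA; returns (records, n_excluded).

    Records containing letters outside the 20-letter alphabet (B, J, O, U, X,
    Z, *) are excluded, counted, and logged.  Headers are parsed as
    ``>accession description``.
    """
    records: list[ProteinRecord] = []
    excluded = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad or not seq:
            excluded += 1
            log.warning("FASTA record %s excluded (illegal letters %s)", rec.id, sorted(bad))
            continue
        m = _HEADER_RE.match(rec.description)
        accession, description = (m.group(1), m.group(2)) if m else (rec.id, "")
        records.append(ProteinRecord(accession=accession, description=description, sequence=seq))
    return records, excluded


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> Path:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return Path(path)


def group_triples(
    spectra: Sequence[Spectrum], precursor_tol: float = 0.01
) -> tuple[list[SpectrumTriple], list[Spectrum]]:
    """Greedy scan-order grouping of CID/HCD/ETD scans into triples.

    A CID scan opens a candidate; the next unconsumed HCD and then ETD scans
    with the same charge and a precursor m/z within ``precursor_tol`` complete
    it.  Each spectrum ends up in at most one triple; everything else is
    returned as unpaired.
    """
    ordered = sorted(spectra, key=lambda s: s.scan)
    consumed: set[int] = set()
    triples: list[SpectrumTriple] = []
    for i, s in enumerate(ordered):
        if i in consumed or s.mode != "CID":
            continue
        found: dict[str, tuple[int, Spectrum]] = {}
        start = i + 1
        for mode in ("HCD", "ETD"):
            for j in range(start, len(ordered)):
                t = ordered[j]
                if (
                    j not in consumed
                    and t.mode == mode
                    and t.precursor_charge == s.precursor_charge
                    and abs(t.precursor_mz - s.precursor_mz) <= precursor_tol
                ):
                    found[mode] = (j, t)
                    start = j + 1
                    break
            if mode not in found:
                break
        if len(found) == 2:
            consumed.update({i, found["HCD"][0], found["ETD"][0]})
            triples.append(SpectrumTriple(cid=s, hcd=found["HCD"][1], etd=found["ETD"][1]))
    unpaired = [s for i, s in enumerate(ordered) if i not in consumed]
    return triples, unpaired


# ---------------------------------------------------------------------------
# Tabular artifacts

PRM_COLUMNS = ["triple_id", "M", "mass", "score", "provenance"]

_MODE_BITS = {"CID": 1, "HCD": 2, "ETD": 4}
_BITS_MODE = {v: k for k, v in _MODE_BITS.items()}


def _bits_to_str(bits: int) -> str:
    return "+".join(name for bit, name in sorted(_BITS_MODE.items()) if bits & bit)


def _str_to_bits(text: str) -> int:
    return sum(_MODE_BITS.get(tok, 0) for tok in str(text).split("+"))


def write_prm_archive(prms: Iterable[PRMSpectrum], path: str | Path) -> Path:
    rows = []
    for p in prms:
        spectrum_prov = "+".join(p.provenance)
        if len(p) == 0:
            rows.append((p.spectrum_id, p.M, np.nan, np.nan, spectrum_prov))
        for i, (m, s) in enumerate(zip(p.masses, p.scores)):
            prov = (
                _bits_to_str(int(p.peak_modes[i]))
                if p.peak_modes is not None
                else spectrum_prov
            )
            rows.append((p.spectrum_id, p.M, float(m), float(s), prov))
    df = pd.DataFrame(rows, columns=PRM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return Path(path)


def read_prm_archive(path: str | Path) -> list[PRMSpectrum]:
    df = pd.read_csv(path, sep="\t", dtype={"triple_id": str, "provenance": str})
    prms = []
    for tid, grp in df.groupby("triple_id", sort=False):
        M = float(grp["M"].iloc[0])
        grp = grp.dropna(subset=["mass"])
        masses = grp["mass"].to_numpy(float)
        order = np.argsort(masses)
        bits = np.array(
            [_str_to_bits(t) for t in grp["provenance"].fillna("")], dtype=np.uint8
        )
        prov = tuple(
            name for bit, name in sorted(_BITS_MODE.items())
            if len(bits) and np.bitwise_or.reduce(bits) & bit
        )
        prms.append(
            PRMSpectrum(
                spectrum_id=str(tid),
                M=M,
                masses=masses[order],
                scores=grp["score"].to_numpy(float)[order],
                provenance=prov,
                peak_modes=bits[order] if len(bits) else None,
            )
        )
    return prms
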