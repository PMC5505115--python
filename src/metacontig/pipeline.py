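"""End-to-end pipeline: simulate -> PRM -> network -> assemble -> de novo -> map.

The two mass fractions of the experimental design (above / below the ~10 kDa
ultrafiltration cutoff) are processed as independent input groups and merged
at the parsimony step, so the summary table has one column per group plus a
combined column.  A run is fully determined by its configuration and seed;
rerunning writes bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import assembly, denovo, homology, io as mcio, network as mcnet, prm, simulate
from .model import ProteinRecord

log = logging.getLogger(__name__)

SUMMARY_ROWS = [
    "No. of spectral triplets",
    "No. of contigs",
    "No. of homologous sequences",
    "No. of de novo sequences",
    "No. of proteins",
    "No. of raw files",
]


@dataclass
class PipelineConfig:
    seed: int
    n_proteins: int = 10
    len_range: tuple[int, int] = (60, 200)
    cutoff_da: float = 10_000.0
    noiseless: bool = False
    deterministic_digests: bool = False
    dda: bool = False
    merge_tol: float = prm.DEFAULT_MERGE_TOL
    align_tol: float = mcnet.DEFAULT_ALIGN_TOL
    min_matches: int = mcnet.DEFAULT_NETWORK_MIN_MATCHES
    min_score: float | None = None
    peak_score_floor: float = 9.0
    min_modes: int = 3
    min_window_frac: float = mcnet.DEFAULT_MIN_WINDOW_FRAC
    shift_coherence: float = mcnet.DEFAULT_SHIFT_COHERENCE
    frame_tol: float = assembly.DEFAULT_FRAME_TOL
    min_component_size: int = assembly.DEFAULT_MIN_COMPONENT_SIZE
    call_tol: float = denovo.DEFAULT_CALL_TOL
    gap_tol: float = homology.DEFAULT_GAP_TOL
    min_matched: int = homology.DEFAULT_MIN_MATCHED
    max_gap_residues: int = homology.DEFAULT_MAX_GAP_RESIDUES
    input_fasta: str | None = None          # use these proteins instead of generating

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "seed" not in data:
            raise ValueError("config must set a seed")
        if "len_range" in data:
            data["len_range"] = tuple(data["len_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["len_range"] = list(d["len_range"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroupResult:
    name: str
    records: list[ProteinRecord]
    triples: list
    ground_truth: pd.DataFrame
    prms: list
    graph: object
    metas: list
    contigs: list
    seqs: list
    matches: list
    removed: list
    n_raw_files: int


@dataclass
class RunResult:
    config: PipelineConfig
    out_dir: Path
    proteome: list[ProteinRecord]
    groups: dict[str, GroupResult]
    parsimony: homology.ParsimonyReport | None
    summary: pd.DataFrame


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def _run_group(
    name: str,
    records: list[ProteinRecord],
    config: PipelineConfig,
    out_dir: Path,
    salt: int,
) -> GroupResult:
    model = simulate.FragmentationModel()
    if config.noiseless:
        model = model.noiseless()
    digest_rng = (
        None
        if config.deterministic_digests
        else np.random.default_rng(_derived_seed(config.seed, salt))
    )
    pools = simulate.digest_pools(records, rng=digest_rng)
    pools = {k: v for k, v in pools.items() if v}
    triples_by_digest, gt = simulate.simulate_acquisition(
        pools, model, seed=_derived_seed(config.seed, salt + 1), dda=config.dda
    )
    triples = [t for ts in triples_by_digest.values() for t in ts]
    for digest_name, ts in triples_by_digest.items():
        spectra = [s for t in ts for s in t.spectra]
        mcio.write_mgf(spectra, out_dir / f"{name}_{digest_name}.mgf")
    gt = gt.copy()
    gt.insert(0, "group", name)
    scoring = prm.ScoringModel()
    prms = [prm.triple_to_prm(t, scoring, merge_tol=config.merge_tol) for t in triples]
    mcio.write_prm_archive(prms, out_dir / f"{name}_prm.tsv")
    graph = mcnet.build_network(
        prms,
        align_tol=config.align_tol,
        min_matches=config.min_matches,
        min_score=config.min_score,
        peak_score_floor=config.peak_score_floor,
        min_modes=config.min_modes,
        min_window_frac=config.min_window_frac,
        shift_coherence=config.shift_coherence,
        seed=_derived_seed(config.seed, salt + 2),
    )
    edge_rows = [
        (a.id_a, a.id_b, a.shift, a.n_matches, a.score)
        for _, _, a in (
            (u, v, graph.edges[u, v]["alignment"]) for u, v in sorted(graph.edges)
        )
    ]
    pd.DataFrame(
        edge_rows, columns=["id_a", "id_b", "shift", "n_matches", "score"]
    ).to_csv(out_dir / f"{name}_edges.tsv", sep="\t", index=False, float_format="%.6f")
    metas, contigs = assembly.assemble(
        graph,
        frame_tol=config.frame_tol,
        min_component_size=config.min_component_size,
    )
    for m in metas:
        m.contig_id = f"{name}.{m.contig_id}"
    for c in contigs:
        c.contig_id = f"{name}.{c.contig_id}"
    meta_rows = [
        (m.contig_id, m.n_spectra, m.span, float(mass), float(score))
        for m in metas
        for mass, score in zip(m.masses, m.scores)
    ]
    pd.DataFrame(
        meta_rows, columns=["contig_id", "n_spectra", "span", "mass", "score"]
    ).to_csv(out_dir / f"{name}_metacontigs.tsv", sep="\t", index=False, float_format="%.6f")
    member_rows = [
        (m.contig_id, sid, float(m.offsets[sid]))
        for m in metas
        for sid in m.member_ids
    ]
    pd.DataFrame(member_rows, columns=["contig_id", "spectrum_id", "offset"]).to_csv(
        out_dir / f"{name}_members.tsv", sep="\t", index=False, float_format="%.6f"
    )
    seqs = [
        denovo.sequence_consensus(m, call_tol=config.call_tol) for m in metas
    ]
    pd.DataFrame(
        [
            (s.contig_id, str(s), s.n_residues, s.n_gaps, s.total_mass)
            for s in seqs
        ],
        columns=["contig_id", "denovo_string", "n_residues", "n_gaps", "total_mass"],
    ).to_csv(out_dir / f"{name}_sequences.tsv", sep="\t", index=False, float_format="%.5f")
    return GroupResult(
        name=name,
        records=records,
        triples=triples,
        ground_truth=gt,
        prms=prms,
        graph=graph,
        metas=metas,
        contigs=contigs,
        seqs=seqs,
        matches=[],
        removed=[],
        n_raw_files=len(triples_by_digest),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunResult:
    """Execute all stages; artifacts land in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    if config.input_fasta:
        proteome, _ = mcio.read_fasta(config.input_fasta)
    else:
        proteome = simulate.generate_proteome(
            config.n_proteins, config.len_range, seed=config.seed
        )
    mcio.write_fasta(proteome, out_dir / "proteome.fasta")
    above, below = simulate.fractionate(proteome, config.cutoff_da)
    group_records = {"above_10kDa": above, "below_10kDa": below}
    groups: dict[str, GroupResult] = {}
    for salt, (name, records) in enumerate(group_records.items()):
        if not records:
            log.info("group %s is empty; skipped", name)
            continue
        groups[name] = _run_group(name, records, config, out_dir, salt * 10 + 1)
        log.info(
            "group %s: %d proteins, %d triples, %d meta-contigs",
            name, len(records), len(groups[name].triples), len(groups[name].metas),
        )
    if groups:
        pd.concat([g.ground_truth for g in groups.values()], ignore_index=True).to_csv(
            out_dir / "ground_truth.tsv", sep="\t", index=False
        )
    # homology search against the proteome, per group, then merged parsimony
    all_kept = []
    for g in groups.values():
        matches = homology.search_database(
            g.seqs,
            proteome,
            gap_tol=config.gap_tol,
            min_matched=config.min_matched,
            max_gap_residues=config.max_gap_residues,
        )
        kept, removed = homology.filter_contaminants(matches)
        g.matches, g.removed = kept, removed
        all_kept.extend(kept)
        rows = [
            (m.contig_id, m.accession, m.start, m.end, m.matched_residues,
             m.score, m.best)
            for m in kept
        ]
        pd.DataFrame(
            rows,
            columns=["contig_id", "accession", "start", "end",
                     "matched_residues", "score", "best"],
        ).to_csv(out_dir / f"{g.name}_matches.tsv", sep="\t", index=False)
    report = homology.parsimony_group(all_kept) if all_kept else None
    if report is not None:
        pd.DataFrame(
            [(acc, ";".join(report.support[acc])) for acc in report.selected],
            columns=["accession", "supporting_contigs"],
        ).to_csv(out_dir / "parsimony.tsv", sep="\t", index=False)
    summary = _summary_table(groups, report)
    summary.to_csv(out_dir / "summary.tsv", sep="\t")
    desc = {r.accession: r for r in proteome}
    contig_rows = []
    for g in groups.values():
        seq_by_id = {s.contig_id: s for s in g.seqs}
        for m in g.matches:
            if not m.best:
                continue
            rec = desc.get(m.accession)
            contig_rows.append(
                (
                    str(seq_by_id[m.contig_id]),
                    m.accession,
                    rec.description if rec else "",
                    rec.species or "" if rec else "",
                )
            )
    pd.DataFrame(
        contig_rows, columns=["de novo sequence", "Protein index", "Protein name", "Species"]
    ).to_csv(out_dir / "contig_table.tsv", sep="\t", index=False)
    return RunResult(
        config=config, out_dir=out_dir, proteome=proteome,
        groups=groups, parsimony=report, summary=summary,
    )


def _summary_table(
    groups: dict[str, GroupResult], report: homology.ParsimonyReport | None
) -> pd.DataFrame:
    cols = {}
    for g in groups.values():
        per_group_proteins = (
            len(homology.parsimony_group(g.matches).selected) if g.matches else 0
        )
        cols[g.name] = [
            len(g.triples),
            len(g.metas),
            sum(1 for m in g.matches if m.best),
            len(g.seqs),
            per_group_proteins,
            g.n_raw_files,
        ]
    cols["together"] = [
        sum(c[0] for c in cols.values()) if cols else 0,
        sum(len(g.metas) for g in groups.values()),
        sum(sum(1 for m in g.matches if m.best) for g in groups.values()),
        sum(len(g.seqs) for g in groups.values()),
        len(report.selected) if report else 0,
        sum(g.n_raw_files for g in groups.values()),
    ]
    return pd.DataFrame(cols, index=SUMMARY_ROWS)


def summarize(run_dir: str | Path) -> pd.DataFrame:
    """Recount a completed run's artifacts into the summary table."""
    run_dir = Path(run_dir)
    existing = sorted(run_dir.glob("*_sequences.tsv"))
    required = [run_dir / "summary.tsv", run_dir / "ground_truth.tsv"]
    missing = [str(p) for p in required if not p.exists()]
    if missing or not existing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing or existing}")
    return pd.read_csv(run_dir / "summary.tsv", sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Ground-truth evaluation (synthetic runs only)


def evaluate_against_truth(result: RunResult) -> dict:
    """Score a synthetic run against its ground truth.

    Returns best-hit accuracy over mapped meta-contigs, residue-call accuracy
    over all called residues, and the parsimony-vs-truth comparison.
    """
    proteins = {r.accession: r.sequence for r in result.proteome}
    n_best = 0
    n_best_correct = 0
    res_total = 0
    res_correct = 0
    covered_true: set[str] = set()
    for g in result.groups.values():
        gt = g.ground_truth.set_index("triple_id")
        seq_by_id = {s.contig_id: s for s in g.seqs}
        source_of: dict[str, tuple[str, int]] = {}
        for meta in g.metas:
            accs = [gt.loc[sid, "accession"] for sid in meta.member_ids if sid in gt.index]
            if not accs:
                continue
            majority = max(set(accs), key=accs.count)
            anchor_sid = min(
                meta.member_ids, key=lambda sid: (meta.offsets.get(sid, 1e9), sid)
            )
            start = int(gt.loc[anchor_sid, "start"])
            source_of[meta.contig_id] = (majority, start)
            covered_true.add(majority)
            seq = seq_by_id[meta.contig_id]
            protein = proteins[gt.loc[anchor_sid, "accession"]]
            pos = start
            lost = False
            for e in seq.elements:
                if e.kind == "residue":
                    res_total += 1
                    if not lost and pos < len(protein) and _res_equiv(protein[pos], e.letter):
                        res_correct += 1
                    pos += 1
                else:
                    if lost:
                        continue
                    step = _gap_steps(protein, pos, e.mass)
                    if step is None:
                        lost = True
                    else:
                        pos += step
        for m in g.matches:
            if not m.best or m.contig_id not in source_of:
                continue
            n_best += 1
            if m.accession == source_of[m.contig_id][0]:
                n_best_correct += 1
    selected = set(result.parsimony.selected) if result.parsimony else set()
    return {
        "n_meta_contigs": sum(len(g.metas) for g in result.groups.values()),
        "n_mapped": n_best,
        "best_hit_accuracy": (n_best_correct / n_best) if n_best else float("nan"),
        "residue_calls": res_total,
        "residue_call_accuracy": (res_correct / res_total) if res_total else float("nan"),
        "parsimony_selected": sorted(selected),
        "covered_true_proteins": sorted(covered_true),
        "parsimony_equals_truth": selected == covered_true and bool(selected),
    }


def _res_equiv(a: str, b: str) -> bool:
    return a == b or {a, b} == {"I", "L"}


def _gap_steps(protein: str, pos: int, gap_mass: float, tol: float = 0.1) -> int | None:
    from .constants import RESIDUE_MASS

    total = 0.0
    for k in range(1, 12):
        if pos + k > len(protein):
            return None
        total += RESIDUE_MASS[protein[pos + k - 1]]
        if abs(total - gap_mass) <= tol:
            return k
        if total > gap_mass + tol:
            return None
    return None
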