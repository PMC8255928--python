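"""End-to-end orchestration: one config, fixed seed, logged provenance.

``run_all`` executes simulate (optional) → catalog → de → network →
cluster → targets → enrich → validate, writing each stage's table under
the output directory plus a manifest recording the config hash, package
version and per-stage row counts. All randomness derives from the single
config seed, so re-running the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import catalog as catalog_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import network as network_mod
from . import targets as targets_mod
from . import validation as validation_mod
from .io import (
    parse_fasta,
    parse_gtf,
    read_expression,
    read_gmt,
    read_group_map,
)
from .simulate import SimConfig, simulate_all

log = logging.getLogger("lncnet")

STAGES = [
    "simulate",
    "catalog",
    "de",
    "network",
    "cluster",
    "targets",
    "enrich",
    "validate",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "lncnet_out"
    seed: int = 0
    simulate: bool = True
    sim: dict[str, Any] = field(default_factory=dict)
    # input paths; filled from the simulate stage when simulate=True
    expression: str | None = None
    groups: str | None = None
    gtf: str | None = None
    fasta: str | None = None
    gmt: str | None = None
    ct: str | None = None
    # thresholds
    alpha: float = 0.05
    fc: float = 2.0
    r_min: float = 0.8
    top_k: int = 500
    window: int = 300_000
    min_pairs: int = 10
    energy_max: float = -50.0
    positive_only: bool = False
    mcl: dict[str, Any] = field(default_factory=dict)
    reference_gene: str = "ACTB"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest dict (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
        simdir = outdir / "sim"
        try:
            simulate_all(sim_cfg, simdir)
        except Exception as exc:  # pragma: no cover - config errors
            raise StageError("simulate", exc) from exc
        cfg.expression = str(simdir / "expression.tsv")
        cfg.groups = str(simdir / "groups.tsv")
        cfg.gtf = str(simdir / "annotation.gtf")
        cfg.fasta = str(simdir / "transcripts.fa")
        cfg.gmt = str(simdir / "genesets.gmt")
        cfg.ct = str(simdir / "ct.tsv")
        manifest["stages"]["simulate"] = {"n_rows": sim_cfg.n_genes + sim_cfg.n_lnc}
        log.info("simulate: wrote inputs to %s", simdir)
    else:
        manifest["stages"]["simulate"] = {"n_rows": 0, "skipped": True}

    # fail before any analysis stage if an input is missing
    for name in ("expression", "groups", "gtf", "fasta", "gmt", "ct"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing input path for {name!r}: {p}")

    def stage(name):
        def deco(fn):
            try:
                n = fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {"n_rows": int(n)}
            log.info("%s: %d rows", name, n)

        return deco

    records = parse_gtf(cfg.gtf)
    seqs = parse_fasta(cfg.fasta)
    group_map = read_group_map(cfg.groups)
    mat = read_expression(cfg.expression, group_map)
    state: dict[str, Any] = {}

    @stage("catalog")
    def _catalog():
        candidates = [r for r in records if r.biotype != "mRNA"]
        lnc_records = catalog_mod.build_catalog(
            candidates, seqs, records, min_len=200
        )
        state["lnc_ids"] = {r.gene_id for r in lnc_records}
        df = pd.DataFrame(
            [
                (r.transcript_id, r.gene_id, r.chrom, r.start, r.end, r.strand,
                 r.biotype, r.length)
                for r in lnc_records
            ],
            columns=["transcript_id", "gene_id", "chrom", "start", "end",
                     "strand", "biotype", "length"],
        )
        _write_tsv(df, outdir / "catalog.tsv")
        return len(df)

    @stage("de")
    def _de():
        de_table = expression_mod.de_test(mat, alpha=cfg.alpha, fc=cfg.fc)
        state["de_table"] = de_table
        _write_tsv(de_table.reset_index(drop=True), outdir / "de.tsv")
        return len(de_table)

    @stage("network")
    def _network():
        de_ids = set(expression_mod.de_gene_ids(state["de_table"]))
        lnc = sorted(de_ids & state["lnc_ids"])
        mrna = sorted(de_ids - state["lnc_ids"])
        edges = network_mod.correlate_pairs(
            mat, lnc, mrna, r_min=cfg.r_min, alpha=cfg.alpha,
            positive_only=cfg.positive_only,
        )
        top = network_mod.select_top_edges(edges, k=cfg.top_k)
        state["edges"] = top
        _write_tsv(network_mod.edges_to_frame(top), outdir / "edges.tsv")
        return len(top)

    @stage("cluster")
    def _cluster():
        params = network_mod.MclParams(**cfg.mcl)
        if state["edges"]:
            assignment = network_mod.mcl(state["edges"], params)
            rows = sorted(assignment.assignments.items())
        else:
            rows = []
        state["clusters"] = dict(rows)
        df = pd.DataFrame(rows, columns=["node_id", "cluster_id"])
        _write_tsv(df, outdir / "clusters.tsv")
        return len(df)

    @stage("targets")
    def _targets():
        by_gene = {r.gene_id: r for r in records}
        de_ids = set(expression_mod.de_gene_ids(state["de_table"]))
        lnc_recs = [by_gene[g] for g in sorted(de_ids & state["lnc_ids"]) if g in by_gene]
        mrna_recs = [by_gene[g] for g in sorted(de_ids - state["lnc_ids"]) if g in by_gene]
        cis = []
        for lnc in lnc_recs:
            cis.extend(targets_mod.cis_targets(lnc, mrna_recs, window=cfg.window))
        hits = targets_mod.scan_pairs(
            seqs, [(e.lnc_id, e.mrna_id) for e in state["edges"]],
            min_pairs=cfg.min_pairs,
        )
        trans = targets_mod.trans_targets(
            state["edges"], hits, cis,
            energy_max=cfg.energy_max, min_pairs=cfg.min_pairs, r_min=cfg.r_min,
            alpha=cfg.alpha,
        )
        state["trans"] = trans
        cis_df = pd.DataFrame(
            [(c.lnc_id, c.mrna_id, c.distance) for c in cis],
            columns=["lnc_id", "mrna_id", "distance"],
        )
        trans_df = pd.DataFrame(
            [(e.lnc_id, e.mrna_id, e.r, e.p, h.paired_bases, h.energy)
             for e, h in trans],
            columns=["lnc_id", "mrna_id", "r", "p", "paired_bases", "energy"],
        )
        _write_tsv(cis_df, outdir / "cis_targets.tsv")
        _write_tsv(trans_df, outdir / "trans_targets.tsv")
        return len(cis_df) + len(trans_df)

    @stage("enrich")
    def _enrich():
        gene_sets = read_gmt(cfg.gmt)
        clustered = set(state["clusters"]) - state["lnc_ids"]
        background = {r.gene_id for r in records if r.biotype == "mRNA"}
        results = enrichment_mod.enrich(
            clustered & background, gene_sets, background
        ) if clustered & background else []
        _write_tsv(enrichment_mod.results_to_frame(results), outdir / "enrichment.tsv")
        return len(results)

    @stage("validate")
    def _validate():
        cts = pd.read_csv(cfg.ct, sep="\t")
        genes = [g for g in cts["gene"].unique() if g != cfg.reference_gene]
        ct_samples = cts["sample"].unique()
        labels_map = {
            s: ("case" if s.startswith("S") else "control") for s in ct_samples
        }
        rel = {}
        rocs = {}
        for g in genes:
            r = validation_mod.ddct_relative_expression(
                cts, g, cfg.reference_gene, labels_map
            )
            rel[g] = r
            rocs[g] = validation_mod.roc_auc(
                r.to_numpy(), [labels_map[s] for s in r.index]
            )
        report: dict[str, Any] = {
            g: {"auc": round(rocs[g].auc, 4), "flipped": rocs[g].flipped}
            for g in genes
        }
        if len(genes) >= 2:
            ranked = sorted(genes, key=lambda g: -rocs[g].auc)
            a, b = ranked[0], ranked[1]
            labels = [labels_map[s] for s in rel[a].index]
            comb = validation_mod.combined_roc(
                rel[a].to_numpy(), rel[b].loc[rel[a].index].to_numpy(), labels
            )
            report["combined"] = {
                "markers": [a, b],
                "auc": round(comb.auc, 4),
                "separation": comb.separation,
            }
        rel_df = pd.DataFrame(rel)
        rel_df.insert(0, "sample", rel_df.index)
        _write_tsv(rel_df.reset_index(drop=True), outdir / "relative_expression.tsv")
        (outdir / "auc_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        return len(genes)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


TOY_SIM = {
    "n_genes": 240,
    "n_lnc": 80,
    "de_fraction": 0.25,
    "module_spec": [[16, 0.92], [12, 0.9]],
    "n_cis_pairs": 8,
    "n_duplex_pairs": 8,
    "tx_len_range": [300, 900],
    "genome_len": 60_000_000,
    "n_chroms": 4,
}


def toy_config(outdir: str | Path, seed: int = 0) -> PipelineConfig:
    """Small self-simulating configuration that runs in seconds."""
    return PipelineConfig(
        outdir=str(outdir), seed=seed, simulate=True, sim=dict(TOY_SIM), top_k=120
    )


__all__ = ["PipelineConfig", "StageError", "STAGES", "run_all", "toy_config"]
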