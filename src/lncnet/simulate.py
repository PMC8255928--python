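"""Synthetic-data generator for every pipeline input.

Emulates the study design the analysis assumes: two groups of six
neutrophil transcriptomes, thousands of genes of which a fraction is
differentially expressed at a >=2-fold effect, coexpression modules of
lncRNAs and mRNAs driven by a shared latent factor (so the expected
pairwise Pearson correlation is controllable), genomic coordinates that
permit within-300-kb lncRNA/mRNA pairs, and transcript sequences carrying
planted reverse-complementary stretches long enough to pass a duplex
screen. Ground truth for all planted structure is returned alongside the
data so every downstream stage can be scored for recovery.

Every generator takes one explicit integer seed; identical configuration
gives bit-identical in-memory results and byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    TranscriptRecord,
    write_expression,
    write_fasta,
    write_gmt,
    write_group_map,
    write_gtf,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults mirror the sequenced study design: 6 cases vs 6 controls,
    ~2,000 genes of which a quarter are lncRNAs, 10% differentially
    expressed at a 4-fold (log2 effect 2) shift, three planted
    coexpression modules with target Pearson r of 0.9, and a 4-chromosome
    toy genome large enough to separate unrelated genes by more than the
    300-kb cis window.
    """

    n_genes: int = 1500  # mRNA genes
    n_lnc: int = 500
    n_per_group: int = 6
    de_fraction: float = 0.10
    log2fc_effect: float = 2.0
    module_spec: tuple[tuple[int, float], ...] = ((20, 0.9), (15, 0.9), (10, 0.85))
    seed: int = 0
    noise_sd: float = 0.3
    genome_len: int = 350_000_000  # per chromosome
    n_chroms: int = 4
    cis_window: int = 300_000
    n_cis_pairs: int = 20
    n_duplex_pairs: int = 20
    duplex_len_range: tuple[int, int] = (25, 40)
    tx_len_range: tuple[int, int] = (500, 5000)

    def __post_init__(self):
        for name in ("n_genes", "n_lnc", "n_per_group", "genome_len", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.de_fraction < 1:
            raise ConfigError("de_fraction must be in [0, 1)")
        for size, r in self.module_spec:
            if size <= 0 or not -1 < r < 1:
                raise ConfigError(f"bad module spec ({size}, {r})")
        if sum(s for s, _ in self.module_spec) > self.n_genes + self.n_lnc:
            raise ConfigError("module sizes exceed total gene count")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    de_gene_ids: set[str] = field(default_factory=set)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    planted_cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_duplex_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    lnc_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["de_gene_ids"] = sorted(self.de_gene_ids)
        Path(path).write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["de_gene_ids"] = set(payload["de_gene_ids"])
        payload["planted_cis_pairs"] = [tuple(p) for p in payload["planted_cis_pairs"]]
        payload["planted_duplex_pairs"] = [
            tuple(p) for p in payload["planted_duplex_pairs"]
        ]
        return cls(**payload)


def _gene_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(1, cfg.n_lnc + 1)]
    mrna = [f"MRNA{i:05d}" for i in range(1, cfg.n_genes + 1)]
    return lnc, mrna


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw a gene x sample FPKM-like matrix with planted DE and modules.

    Gene abundance is log-normal: log2 x = mu_g + noise, with noise_sd the
    log-scale SD. Module genes share a per-sample latent factor z with
    loading sqrt(r), so the expected pairwise Pearson correlation inside a
    module equals the module's target r. DE genes get +/- log2fc_effect
    added in the case group; module members are drawn from the DE set with
    a common sign so planted modules survive the DE filter into the
    coexpression network.
    """
    rng = np.random.default_rng(cfg.seed)
    lnc_ids, mrna_ids = _gene_ids(cfg)
    genes = lnc_ids + mrna_ids
    n_total = len(genes)
    n_samples = 2 * cfg.n_per_group
    samples = [f"C{i+1}" for i in range(cfg.n_per_group)] + [
        f"S{i+1}" for i in range(cfg.n_per_group)
    ]
    groups = {s: ("control" if s.startswith("C") else "case") for s in samples}
    case_mask = np.array([groups[s] == "case" for s in samples])

    truth = SimTruth(lnc_ids=list(lnc_ids), mrna_ids=list(mrna_ids))

    # choose DE genes from both biotypes proportionally
    n_de_lnc = int(round(cfg.de_fraction * cfg.n_lnc))
    n_de_mrna = int(round(cfg.de_fraction * cfg.n_genes))
    de_lnc = list(rng.choice(lnc_ids, size=n_de_lnc, replace=False))
    de_mrna = list(rng.choice(mrna_ids, size=n_de_mrna, replace=False))
    de_ids = de_lnc + de_mrna
    signs = rng.choice([-1.0, 1.0], size=len(de_ids))
    truth.de_gene_ids = set(de_ids)
    truth.de_log2fc = {g: float(s * cfg.log2fc_effect) for g, s in zip(de_ids, signs)}

    # modules: half lncRNAs, half mRNAs, drawn from the DE set, common sign
    needed = sum(s for s, _ in cfg.module_spec)
    if needed > len(de_ids) and needed > 0:
        raise ConfigError(
            "module sizes exceed the number of DE genes; raise de_fraction"
        )
    free_lnc = [g for g in de_lnc]
    free_mrna = [g for g in de_mrna]
    for mod_id, (size, _r) in enumerate(cfg.module_spec):
        n_l = size // 2
        n_m = size - n_l
        if n_l > len(free_lnc) or n_m > len(free_mrna):
            raise ConfigError("not enough DE genes of each biotype for modules")
        members = free_lnc[:n_l] + free_mrna[:n_m]
        del free_lnc[:n_l], free_mrna[:n_m]
        sign = float(rng.choice([-1.0, 1.0]))
        for g in members:
            truth.module_assignments[g] = mod_id
            truth.de_log2fc[g] = sign * cfg.log2fc_effect

    mu = rng.normal(5.0, 1.5, size=n_total)
    eps = rng.standard_normal((n_total, n_samples))
    log2x = mu[:, None] + cfg.noise_sd * eps

    # latent shared factors for modules
    module_z = {m: rng.standard_normal(n_samples) for m in range(len(cfg.module_spec))}
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, m in truth.module_assignments.items():
        r = cfg.module_spec[m][1]
        i = gene_index[g]
        load = np.sign(r) * np.sqrt(abs(r))
        log2x[i] = mu[i] + cfg.noise_sd * (
            load * module_z[m] + np.sqrt(1 - abs(r)) * eps[i]
        )
    for g, fc in truth.de_log2fc.items():
        log2x[gene_index[g], case_mask] += fc

    values = pd.DataFrame(2.0 ** log2x, index=genes, columns=samples)
    return ExpressionMatrix(values, groups, unit="FPKM"), truth


def simulate_annotation(cfg: SimConfig, truth: SimTruth) -> list[TranscriptRecord]:
    """Place every gene on the toy genome.

    Genes occupy disjoint slots spaced more than the cis window apart, so
    two genes are within the window if and only if they share a slot.
    Planted cis pairs (lncRNA, mRNA) share a slot with a gap below the
    window; all other pairs end up farther apart or on other chromosomes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = truth.lnc_ids + truth.mrna_ids
    # slot content is at most tx + (window-1) gap + tx, so this spacing
    # leaves > window between genes of different slots on one chromosome
    slot = 2 * cfg.cis_window + 4 * cfg.tx_len_range[1]
    slots_per_chrom = cfg.genome_len // slot
    n_cis = min(cfg.n_cis_pairs, len(truth.lnc_ids), len(truth.mrna_ids))
    n_slots_needed = len(genes) - n_cis
    if slots_per_chrom * cfg.n_chroms < n_slots_needed:
        raise ConfigError(
            f"genome too small: need {n_slots_needed} slots of {slot} bp, "
            f"have {slots_per_chrom * cfg.n_chroms}"
        )

    # prefer DE genes for cis pairs so they survive into the network stage
    de_lnc = sorted(truth.de_gene_ids & set(truth.lnc_ids))
    de_mrna = sorted(truth.de_gene_ids & set(truth.mrna_ids))
    cis_lnc = (de_lnc + [g for g in truth.lnc_ids if g not in truth.de_gene_ids])[:n_cis]
    cis_mrna = (de_mrna + [g for g in truth.mrna_ids if g not in truth.de_gene_ids])[:n_cis]
    truth.planted_cis_pairs = list(zip(cis_lnc, cis_mrna))

    paired = {g for pair in truth.planted_cis_pairs for g in pair}
    slot_occupants: list[tuple[str, ...]] = list(truth.planted_cis_pairs)
    slot_occupants += [(g,) for g in genes if g not in paired]

    records: list[TranscriptRecord] = []
    lnc_set = set(truth.lnc_ids)
    for idx, occupants in enumerate(slot_occupants):
        chrom = f"chr{idx % cfg.n_chroms + 1}"
        slot_start = (idx // cfg.n_chroms) * slot + 1
        pos = slot_start
        for j, g in enumerate(occupants):
            tx_len = int(rng.integers(cfg.tx_len_range[0], cfg.tx_len_range[1] + 1))
            start = pos
            end = start + tx_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                ("lncRNA_known" if rng.random() < 0.7 else "lncRNA_novel")
                if g in lnc_set
                else "mRNA"
            )
            records.append(
                TranscriptRecord(
                    transcript_id=f"{g}.t1",
                    gene_id=g,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotype,
                )
            )
            if j + 1 < len(occupants):  # place partner within the window
                gap = int(rng.integers(1000, cfg.cis_window - 1))
                pos = end + gap + 1
            # sanity: everything stays inside the slot
        if records[-1].end > slot_start + slot - 1:
            raise ConfigError("slot overflow; enlarge genome_len")
    order = {g: i for i, g in enumerate(genes)}
    records.sort(key=lambda r: order[r.gene_id])
    return records


def simulate_sequences(
    truth: SimTruth,
    lengths: Mapping[str, int],
    seed: int = 0,
    duplex_len_range: tuple[int, int] = (25, 40),
    n_duplex_pairs: int = 20,
) -> dict[str, str]:
    """Random transcript sequences with planted reverse-complementary
    stretches between the recorded duplex pairs.

    Each planted (lncRNA, mRNA) pair shares an exact reverse-complementary
    stretch whose length is recorded in the truth; all other sequence is
    i.i.d. uniform over ACGT.
    """
    rng = np.random.default_rng(seed + 2)
    bases = np.array(list("ACGT"))
    seqs = {
        g: "".join(rng.choice(bases, size=int(n))) for g, n in lengths.items()
    }
    # pair within coexpression modules first (those pairs also carry a
    # coexpression edge, so they can pass the trans screen), then pad with
    # the remaining DE genes
    lnc_set, mrna_set = set(truth.lnc_ids), set(truth.mrna_ids)
    modules: dict[int, tuple[list[str], list[str]]] = {}
    for g, m in sorted(truth.module_assignments.items()):
        side = 0 if g in lnc_set else 1
        modules.setdefault(m, ([], []))[side].append(g)
    pairs: list[tuple[str, str]] = []
    for m in sorted(modules):
        pairs.extend(zip(modules[m][0], modules[m][1]))
    in_module = {g for p in pairs for g in p}
    extra_lnc = [g for g in sorted(truth.de_gene_ids & lnc_set) if g not in in_module]
    extra_mrna = [g for g in sorted(truth.de_gene_ids & mrna_set) if g not in in_module]
    pairs.extend(zip(extra_lnc, extra_mrna))
    pairs = [(l, m) for l, m in pairs if l in seqs and m in seqs]
    n_pairs = min(n_duplex_pairs, len(pairs))
    truth.planted_duplex_pairs = []
    lo, hi = duplex_len_range
    for lnc, mrna in pairs[:n_pairs]:
        L = int(rng.integers(lo, hi + 1))
        if L > len(seqs[lnc]) or L > len(seqs[mrna]):
            raise ConfigError("planted complement longer than transcript")
        stretch = "".join(rng.choice(bases, size=L))
        pos_m = int(rng.integers(0, len(seqs[mrna]) - L + 1))
        pos_l = int(rng.integers(0, len(seqs[lnc]) - L + 1))
        sm = seqs[mrna]
        seqs[mrna] = sm[:pos_m] + stretch + sm[pos_m + L:]
        sl = seqs[lnc]
        seqs[lnc] = sl[:pos_l] + reverse_complement(stretch) + sl[pos_l + L:]
        truth.planted_duplex_pairs.append((lnc, mrna, L))
    return seqs


def simulate_ct_table(
    truth: SimTruth,
    n_per_group: int,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    reference_gene: str = "ACTB",
    replicate_sd: float = 0.15,
    sample_sd: float = 0.4,
) -> pd.DataFrame:
    """qRT-PCR Ct table: 3 technical replicates per (sample, gene).

    The reference gene is near-constant across samples; each assayed gene's
    case-group Ct is shifted by minus its planted log2 fold change, so the
    2^-ddCt estimate recovers the planted effect.
    """
    if n_per_group <= 1:
        raise ConfigError("n_per_group must be > 1")
    rng = np.random.default_rng(seed + 3)
    if genes is None:
        genes = sorted(truth.de_gene_ids)[:6]
    samples = [f"C{i+1}" for i in range(n_per_group)] + [
        f"S{i+1}" for i in range(n_per_group)
    ]
    rows = []
    base_ct = {g: float(rng.uniform(22, 28)) for g in genes}
    for s in samples:
        is_case = s.startswith("S")
        ref_ct = 20.0 + rng.normal(0, 0.05)
        for rep in range(1, 4):
            rows.append((s, reference_gene, rep, ref_ct + rng.normal(0, replicate_sd)))
        for g in genes:
            ct = base_ct[g] + rng.normal(0, sample_sd)
            if is_case:
                ct -= truth.de_log2fc.get(g, 0.0)
            for rep in range(1, 4):
                rows.append((s, g, rep, ct + rng.normal(0, replicate_sd)))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def simulate_gene_sets(
    truth: SimTruth,
    seed: int = 0,
    n_terms: int = 10,
    term_size_range: tuple[int, int] = (15, 60),
) -> list[GeneSet]:
    """Gene sets over the mRNA universe with one term enriched for the
    module mRNAs (so term enrichment has signal to find)."""
    rng = np.random.default_rng(seed + 4)
    universe = np.array(truth.mrna_ids)
    module_mrna = sorted(
        g for g in truth.module_assignments if g in set(truth.mrna_ids)
    )
    sets = []
    lo, hi = term_size_range
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(universe, size=size, replace=False))
        if i == 0 and module_mrna:
            members |= set(module_mrna)
        sets.append(GeneSet(f"TERM{i:03d}", f"synthetic process {i}", frozenset(members)))
    return sets


def simulate_all(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate and write every pipeline input to ``outdir``.

    Emits expression.tsv, groups.tsv, annotation.gtf, transcripts.fa,
    ct.tsv, genesets.gmt and truth.json; byte-identical across reruns of
    the same configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat, truth = simulate_expression(cfg)
    records = simulate_annotation(cfg, truth)
    lengths = {r.gene_id: r.length for r in records}
    seqs = simulate_sequences(
        truth,
        lengths,
        seed=cfg.seed,
        duplex_len_range=cfg.duplex_len_range,
        n_duplex_pairs=cfg.n_duplex_pairs,
    )
    ct = simulate_ct_table(truth, cfg.n_per_group, seed=cfg.seed)
    sets = simulate_gene_sets(truth, seed=cfg.seed)
    write_expression(mat, outdir / "expression.tsv")
    write_group_map(mat.group_labels, outdir / "groups.tsv")
    write_gtf(records, outdir / "annotation.gtf")
    write_fasta(seqs, outdir / "transcripts.fa")
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False, lineterminator="\n")
    write_gmt(sets, outdir / "genesets.gmt")
    truth.to_json(outdir / "truth.json")
    return truth


__all__ = [
    "ConfigError",
    "SimConfig",
    "SimTruth",
    "reverse_complement",
    "simulate_all",
    "simulate_annotation",
    "simulate_ct_table",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_sequences",
]
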