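"""lncRNA identification: length/location filters, coding-potential
consensus, and known-vs-novel classification against a reference
annotation.

The identification scheme follows the standard cascade: assembled
candidates are filtered on exonic length (>= 200 nt, the conventional
lncRNA definition) and genomic location (fragments contained in
protein-coding exons on the same strand are discarded), then only
transcripts that every coding-potential predictor calls noncoding are
retained (intersection rule). External predictors (pfam/CNCI/PLEK/CPC)
are pluggable; a deterministic ORF-length stub is built in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .io import TranscriptRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    predictor: str
    is_coding: bool


def filter_candidates(
    records: Sequence[TranscriptRecord],
    coding_reference: Sequence[TranscriptRecord] = (),
    min_len: int = 200,
    min_exons: int = 1,
) -> list[TranscriptRecord]:
    """Length and location filter.

    Keeps transcripts with exonic length >= ``min_len`` (inclusive) and at
    least ``min_exons`` exons, then removes any candidate whose span is
    fully contained within an exon of a protein-coding reference
    transcript on the same chromosome and strand — such candidates are
    most plausibly mRNA fragments, not independent lncRNAs.
    """
    coding_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ref in coding_reference:
        if ref.biotype != "mRNA":
            continue
        coding_exons.setdefault((ref.chrom, ref.strand), []).extend(ref.exons)

    def contained(rec: TranscriptRecord) -> bool:
        for s, e in coding_exons.get((rec.chrom, rec.strand), ()):
            if s <= rec.start and rec.end <= e:
                return True
        return False

    return [
        r
        for r in records
        if r.length >= min_len and len(r.exons) >= min_exons and not contained(r)
    ]


def consensus_noncoding(
    calls: Iterable[CodingCall], predictors: set[str]
) -> set[str]:
    """Transcripts that every listed predictor calls noncoding.

    A missing (transcript, predictor) call is an error: the consensus is
    only meaningful over complete call tables.
    """
    table: dict[str, dict[str, bool]] = {}
    for c in calls:
        table.setdefault(c.transcript_id, {})[c.predictor] = c.is_coding
    out = set()
    for tid, row in table.items():
        missing = predictors - row.keys()
        if missing:
            raise ValueError(f"{tid}: missing calls from {sorted(missing)}")
        if not any(row[p] for p in predictors):
            out.add(tid)
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_novelty(
    candidates: Sequence[TranscriptRecord],
    reference: Sequence[TranscriptRecord],
    min_overlap_frac: float = 0.5,
) -> dict[str, str]:
    """known iff same-strand exonic overlap with any reference lncRNA
    covers >= ``min_overlap_frac`` of the candidate's exonic length."""
    ref_by_key: dict[tuple[str, str], list[TranscriptRecord]] = {}
    for ref in reference:
        if ref.biotype in ("lncRNA_known", "lncRNA_novel", "candidate"):
            ref_by_key.setdefault((ref.chrom, ref.strand), []).append(ref)
    out = {}
    for cand in candidates:
        best = 0
        for ref in ref_by_key.get((cand.chrom, cand.strand), ()):
            shared = sum(
                _overlap(ce, re) for ce in cand.exons for re in ref.exons
            )
            best = max(best, shared)
        frac = best / cand.length
        out[cand.transcript_id] = "known" if frac >= min_overlap_frac else "novel"
    return out


def longest_orf(sequence: str) -> int:
    """Length (nt, incl. stop) of the longest ATG→in-frame-stop ORF over
    the three forward frames."""
    seq = sequence.upper().replace("U", "T")
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def builtin_coding_stub(
    sequence: str, transcript_id: str = "", min_orf: int = 300
) -> CodingCall:
    """Deterministic coding-potential stand-in: coding iff the longest ORF
    is >= ``min_orf`` nt."""
    return CodingCall(transcript_id, "orf_stub", longest_orf(sequence) >= min_orf)


def build_catalog(
    candidates: Sequence[TranscriptRecord],
    sequences: Mapping[str, str],
    reference: Sequence[TranscriptRecord],
    predictors: Mapping[str, Callable[[str], bool]] | None = None,
    min_len: int = 200,
    min_overlap_frac: float = 0.5,
) -> list[TranscriptRecord]:
    """Full identification cascade: filter → predictor consensus → novelty.

    ``predictors`` maps predictor name to a callable(sequence) -> is_coding;
    defaults to the built-in ORF stub alone. Returns records re-labelled
    lncRNA_known / lncRNA_novel. Output is always a subset of the filter
    output.
    """
    if predictors is None:
        predictors = {"orf_stub": lambda s: longest_orf(s) >= 300}
    coding_ref = [r for r in reference if r.biotype == "mRNA"]
    lnc_ref = [r for r in reference if r.biotype != "mRNA"]
    filtered = filter_candidates(candidates, coding_ref, min_len=min_len)
    calls = [
        CodingCall(rec.transcript_id, name, fn(sequences[rec.gene_id]))
        for rec in filtered
        if rec.gene_id in sequences
        for name, fn in predictors.items()
    ]
    keep = consensus_noncoding(calls, set(predictors))
    kept = [r for r in filtered if r.transcript_id in keep]
    novelty = classify_novelty(kept, lnc_ref, min_overlap_frac=min_overlap_frac)
    out = []
    for r in kept:
        biotype = "lncRNA_known" if novelty[r.transcript_id] == "known" else "lncRNA_novel"
        out.append(
            TranscriptRecord(
                r.transcript_id, r.gene_id, r.chrom, r.start, r.end,
                r.strand, biotype, r.length, r.exons,
            )
        )
    return out


__all__ = [
    "CodingCall",
    "build_catalog",
    "builtin_coding_stub",
    "classify_novelty",
    "consensus_noncoding",
    "filter_candidates",
    "longest_orf",
]
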