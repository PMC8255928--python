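"""cis and trans lncRNA target inference.

A cis target is a gene on the lncRNA's chromosome within 300 kb (gap
between transcript spans, inclusive; 0 when the spans overlap). A trans
target must show a strong coexpression edge (|r| > 0.8, p < 0.05) AND a
predicted RNA–RNA duplex with at least 10 paired bases and binding energy
at or below the threshold (−50 in the scorer's units; binding energies
are negative, more negative = stronger). cis pairs are excluded from
trans calls, so the two call sets are disjoint by construction.

The duplex scorer is a simplified additive seed-and-extend scanner over
ungapped antiparallel alignments — an interface point where a
thermodynamic external tool can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import TranscriptRecord
from .network import CoexpressionEdge

# pair scores (pseudo free-energy contributions; more negative = stronger)
PAIR_SCORE = {
    ("G", "C"): -3, ("C", "G"): -3,
    ("A", "T"): -2, ("T", "A"): -2,
    ("G", "T"): -1, ("T", "G"): -1,  # wobble
}
MISMATCH = 4
SEED_LEN = 6
_WC = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")}

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
_SCORE_LUT = np.full((5, 5), MISMATCH, dtype=np.int8)
for (_x, _y), _s in PAIR_SCORE.items():
    _SCORE_LUT[_ENC[ord(_x)], _ENC[ord(_y)]] = _s
_WC_LUT = np.zeros((5, 5), dtype=bool)
for _x, _y in _WC:
    _WC_LUT[_ENC[ord(_x)], _ENC[ord(_y)]] = True


@dataclass(frozen=True)
class CisPair:
    lnc_id: str
    mrna_id: str
    distance: int  # bp gap between spans; 0 if overlapping
    same_chrom: bool = True


@dataclass(frozen=True)
class DuplexHit:
    lnc_id: str
    mrna_id: str
    paired_bases: int
    energy: float
    lnc_span: tuple[int, int]  # 0-based half-open within the lncRNA sequence
    mrna_span: tuple[int, int]


def span_distance(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Gap in bp between two transcript spans; 0 when they overlap."""
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def cis_targets(
    lnc: TranscriptRecord,
    genes: Sequence[TranscriptRecord],
    window: int = 300_000,
    require_coexpr: bool = False,
    edges: Sequence[CoexpressionEdge] = (),
) -> list[CisPair]:
    """Genes on the lncRNA's chromosome within ``window`` bp (inclusive).

    With ``require_coexpr`` the pairs are additionally restricted to those
    present in the coexpression edge set (either sign of r).
    """
    edge_keys = {(e.lnc_id, e.mrna_id) for e in edges}
    out = []
    for g in genes:
        if g.gene_id == lnc.gene_id or g.chrom != lnc.chrom:
            continue
        d = span_distance(lnc, g)
        if d > window:
            continue
        if require_coexpr and (lnc.gene_id, g.gene_id) not in edge_keys:
            continue
        out.append(CisPair(lnc.gene_id, g.gene_id, d))
    return out


def duplex_scan(
    seq_a: str,
    seq_b: str,
    min_pairs: int = 10,
    lnc_id: str = "a",
    mrna_id: str = "b",
) -> DuplexHit | None:
    """Best ungapped antiparallel duplex between two sequences.

    Seeds are runs of >= 6 consecutive exact Watson–Crick pairs; each seed
    is extended in both directions while the score improves, i.e. while
    the next pair is complementary (G·C −3, A·T −2, G·T wobble −1). A
    mismatch would add +4 and therefore terminates extension. The hit with
    the lowest (best) total energy is returned, with ``paired_bases`` the
    number of paired positions; ``None`` when no stretch reaches
    ``min_pairs``.

    Antiparallel pairing means position i of ``seq_a`` pairs with position
    j of ``seq_b`` and i+1 pairs with j−1; equivalently the scan runs over
    the diagonals of ``seq_a`` against reversed ``seq_b``.
    """
    a = seq_a.upper().replace("U", "T")
    b_rev = seq_b.upper().replace("U", "T")[::-1]
    la, lb = len(a), len(b_rev)
    if la < SEED_LEN or lb < SEED_LEN:
        return None
    ea = _ENC[np.frombuffer(a.encode("ascii"), dtype=np.uint8)]
    eb = _ENC[np.frombuffer(b_rev.encode("ascii"), dtype=np.uint8)]
    scores = _SCORE_LUT[ea[:, None], eb[None, :]]
    wc = _WC_LUT[ea[:, None], eb[None, :]]
    best: DuplexHit | None = None
    for off in range(-(lb - 1), la):
        # diagonal: a[i] paired with b_rev[i - off]
        diag_s = np.diagonal(scores, offset=-off)
        run = diag_s.shape[0]
        if run < SEED_LEN:
            continue
        diag_wc = np.diagonal(wc, offset=-off)
        valid = diag_s < 0
        if not valid.any():
            continue
        # maximal mismatch-free segments along the diagonal
        bounds = np.flatnonzero(np.diff(valid.astype(np.int8)))
        starts = [0] if valid[0] else []
        starts += [int(i) + 1 for i in bounds if not valid[i]]
        ends = [int(i) + 1 for i in bounds if valid[i]]
        if valid[-1]:
            ends.append(run)
        i0 = max(0, off)
        j0 = i0 - off
        for start, end in zip(starts, ends):
            n_pairs = end - start
            if n_pairs < max(min_pairs, SEED_LEN):
                continue
            # seed: >= SEED_LEN consecutive exact Watson-Crick pairs
            w = diag_wc[start:end].astype(np.int8)
            consec, seeded = 0, False
            for flag in w:
                consec = consec + 1 if flag else 0
                if consec >= SEED_LEN:
                    seeded = True
                    break
            if not seeded:
                continue
            energy = float(diag_s[start:end].sum())
            if best is None or energy < best.energy:
                ia, ja = i0 + start, j0 + start
                best = DuplexHit(
                    lnc_id,
                    mrna_id,
                    n_pairs,
                    energy,
                    (ia, ia + n_pairs),
                    (len(seq_b) - (ja + n_pairs), len(seq_b) - ja),
                )
    return best


def scan_pairs(
    sequences: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    min_pairs: int = 10,
) -> list[DuplexHit]:
    """Run the duplex scanner over (lnc_id, mrna_id) pairs."""
    hits = []
    for lnc, mrna in pairs:
        if lnc not in sequences or mrna not in sequences:
            continue
        hit = duplex_scan(
            sequences[lnc], sequences[mrna], min_pairs=min_pairs,
            lnc_id=lnc, mrna_id=mrna,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def trans_targets(
    edges: Sequence[CoexpressionEdge],
    hits: Sequence[DuplexHit],
    cis_pairs: Sequence[CisPair] = (),
    energy_max: float = -50.0,
    min_pairs: int = 10,
    r_min: float = 0.8,
    alpha: float = 0.05,
) -> list[tuple[CoexpressionEdge, DuplexHit]]:
    """Pairs passing coexpression AND duplex screens, minus cis pairs."""
    cis_keys = {(c.lnc_id, c.mrna_id) for c in cis_pairs}
    hit_by_key = {(h.lnc_id, h.mrna_id): h for h in hits}
    out = []
    for e in edges:
        key = (e.lnc_id, e.mrna_id)
        if key in cis_keys or abs(e.r) < r_min or e.p >= alpha:
            continue
        h = hit_by_key.get(key)
        if h is None or h.paired_bases < min_pairs or h.energy > energy_max:
            continue
        out.append((e, h))
    return out


__all__ = [
    "CisPair",
    "DuplexHit",
    "MISMATCH",
    "PAIR_SCORE",
    "SEED_LEN",
    "cis_targets",
    "duplex_scan",
    "scan_pairs",
    "span_distance",
    "trans_targets",
]
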