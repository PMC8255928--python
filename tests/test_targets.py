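import numpy as np
import pytest

from lncnet.io import TranscriptRecord
from lncnet.network import CoexpressionEdge
from lncnet.simulate import reverse_complement
from lncnet.targets import (
    PAIR_SCORE,
    SEED_LEN,
    CisPair,
    DuplexHit,
    cis_targets,
    duplex_scan,
    span_distance,
    trans_targets,
)


def rec(gene, chrom, start, end, strand="+", biotype="mRNA"):
    return TranscriptRecord(f"{gene}.t1", gene, chrom, start, end, strand, biotype)


def brute_force_best_duplex(seq_a: str, seq_b: str, min_pairs: int):
    """Exhaustive oracle over every ungapped antiparallel alignment.

    Enumerates all (i, j, L) substring alignments of seq_a against
    reversed seq_b, keeps those made only of complementary pairs
    (including wobble), containing >= SEED_LEN consecutive exact
    Watson-Crick pairs, with length >= min_pairs; returns the minimal
    total energy or None.
    """
    wc = {("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")}
    a = seq_a.upper()
    b_rev = seq_b.upper()[::-1]
    best = None
    for i in range(len(a)):
        for j in range(len(b_rev)):
            energy = 0
            consec = 0
            seeded = False
            L = 0
            while i + L < len(a) and j + L < len(b_rev):
                pair = (a[i + L], b_rev[j + L])
                if pair not in PAIR_SCORE:
                    break
                energy += PAIR_SCORE[pair]
                consec = consec + 1 if pair in wc else 0
                seeded = seeded or consec >= SEED_LEN
                L += 1
                if seeded and L >= min_pairs:
                    if best is None or energy < best:
                        best = energy
    return best


class TestCisTargets:
    def test_distance_symmetric_and_zero_on_overlap(self):
        a = rec("a", "chr1", 100, 500)
        b = rec("b", "chr1", 900, 1200)
        c = rec("c", "chr1", 400, 950)
        assert span_distance(a, b) == span_distance(b, a) == 399
        assert span_distance(a, c) == 0

    @pytest.mark.parametrize("gap,included", [(300_000, True), (300_001, False)])
    def test_window_boundary_inclusive(self, gap, included):
        lnc = rec("lnc", "chr1", 1000, 2000, biotype="lncRNA_known")
        mrna = rec("m", "chr1", 2000 + gap + 1, 2000 + gap + 5000)
        pairs = cis_targets(lnc, [mrna], window=300_000)
        assert bool(pairs) is included
        if included:
            assert pairs[0].distance == gap

    def test_cross_chromosome_never_called(self):
        lnc = rec("lnc", "chr1", 1000, 2000, biotype="lncRNA_known")
        mrna = rec("m", "chr2", 1000, 2000)
        assert cis_targets(lnc, [mrna]) == []

    def test_require_coexpr_filters_to_edges(self):
        lnc = rec("lnc", "chr1", 1000, 2000, biotype="lncRNA_known")
        near = [rec("m1", "chr1", 5000, 6000), rec("m2", "chr1", 8000, 9000)]
        edges = [CoexpressionEdge("lnc", "m2", -0.9, 0.01)]
        pairs = cis_targets(lnc, near, require_coexpr=True, edges=edges)
        assert [p.mrna_id for p in pairs] == ["m2"]

    def test_planted_pairs_recovered_exactly(self, small_cfg, small_sim):
        from lncnet.simulate import simulate_annotation

        _, truth = small_sim
        records = simulate_annotation(small_cfg, truth)
        by_gene = {r.gene_id: r for r in records}
        mrna_recs = [by_gene[g] for g in truth.mrna_ids]
        called = set()
        for lnc_id in truth.lnc_ids:
            for p in cis_targets(by_gene[lnc_id], mrna_recs, window=small_cfg.cis_window):
                called.add((p.lnc_id, p.mrna_id))
        assert called == set(truth.planted_cis_pairs)


class TestDuplexScan:
    def test_planted_reverse_complement_found(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), 60))
        stretch = a[20:32]  # 12 nt
        b = "".join(rng.choice(list(bases), 20)) + reverse_complement(stretch) + \
            "".join(rng.choice(list(bases), 20))
        hit = duplex_scan(a, b, min_pairs=10)
        assert hit is not None and hit.paired_bases >= 12

    def test_eight_base_complement_fails_min_pairs(self):
        a = "AAAAAAAAAAGGGCCGGATCAAAAAAAAAA"
        core = a[10:18]
        b = "TTTT" + reverse_complement(core) + "TTTT"
        # poly-A vs poly-T tails could pair; use G/C tails instead
        b = "GGGG" + reverse_complement(core) + "GGGG"
        hit = duplex_scan(a, b, min_pairs=10)
        if hit is not None:
            # any hit must involve more than the 8-nt core
            assert hit.paired_bases >= 10

    def test_full_reverse_complement_pairs_whole_sequence(self):
        seq = "GATTACAGGCCTTAGC"
        hit = duplex_scan(seq, reverse_complement(seq), min_pairs=10)
        assert hit is not None
        assert hit.paired_bases == len(seq)
        expected = sum(PAIR_SCORE[(c, {"A": "T", "T": "A", "C": "G", "G": "C"}[c])]
                       for c in seq)
        assert hit.energy == expected

    def test_short_sequence_gives_no_hit(self):
        assert duplex_scan("ACGT", "ACGT", min_pairs=10) is None

    @pytest.mark.parametrize("min_pairs", [8, 10])
    def test_matches_exhaustive_oracle_on_short_sequences(self, min_pairs):
        rng = np.random.default_rng(7)
        bases = list("ACGT")
        n_with_hits = 0
        for trial in range(60):
            la, lb = rng.integers(15, 41, size=2)
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            if trial % 3 == 0:  # plant a stretch so hits occur regularly
                k = int(rng.integers(10, 14))
                k = min(k, la, lb)
                start = int(rng.integers(0, la - k + 1))
                sub = a[start : start + k]
                pos = int(rng.integers(0, lb - k + 1))
                b = b[:pos] + reverse_complement(sub) + b[pos + k:]
            expected = brute_force_best_duplex(a, b, min_pairs)
            hit = duplex_scan(a, b, min_pairs=min_pairs)
            got = None if hit is None else hit.energy
            assert got == expected, (a, b)
            n_with_hits += got is not None
        assert n_with_hits >= 10  # the oracle comparison exercised real hits


class TestTransTargets:
    EDGE = CoexpressionEdge("l1", "m1", 0.9, 0.001)
    HIT = DuplexHit("l1", "m1", 25, -60.0, (0, 25), (0, 25))

    def test_pair_meeting_all_criteria_returned(self):
        assert trans_targets([self.EDGE], [self.HIT]) == [(self.EDGE, self.HIT)]

    @pytest.mark.parametrize(
        "edge,hit",
        [
            (CoexpressionEdge("l1", "m1", 0.5, 0.001), HIT),  # weak correlation
            (CoexpressionEdge("l1", "m1", 0.9, 0.2), HIT),  # not significant
            (EDGE, DuplexHit("l1", "m1", 8, -60.0, (0, 8), (0, 8))),  # few pairs
            (EDGE, DuplexHit("l1", "m1", 25, -30.0, (0, 25), (0, 25))),  # weak energy
        ],
    )
    def test_failing_any_criterion_excluded(self, edge, hit):
        assert trans_targets([edge], [hit]) == []

    def test_strong_duplex_without_edge_excluded(self):
        assert trans_targets([], [self.HIT]) == []

    def test_cis_pairs_excluded_so_sets_disjoint(self):
        cis = [CisPair("l1", "m1", 1000)]
        assert trans_targets([self.EDGE], [self.HIT], cis_pairs=cis) == []

    def test_planted_duplex_module_pairs_recovered(self, small_cfg, small_sim):
        from lncnet.network import correlate_pairs
        from lncnet.simulate import simulate_annotation, simulate_sequences
        from lncnet.targets import scan_pairs

        mat, truth = small_sim
        records = simulate_annotation(small_cfg, truth)
        lengths = {r.gene_id: r.length for r in records}
        seqs = simulate_sequences(
            truth, lengths, seed=small_cfg.seed,
            duplex_len_range=small_cfg.duplex_len_range,
            n_duplex_pairs=small_cfg.n_duplex_pairs,
        )
        lnc_set = set(truth.lnc_ids)
        module = sorted(truth.module_assignments)
        edges = correlate_pairs(
            mat, [g for g in module if g in lnc_set],
            [g for g in module if g not in lnc_set],
        )
        planted_in_modules = [
            (l, m) for l, m, _ in truth.planted_duplex_pairs
            if l in truth.module_assignments and m in truth.module_assignments
        ]
        assert planted_in_modules
        hits = scan_pairs(seqs, planted_in_modules)
        trans = trans_targets(edges, hits)
        recovered = {(e.lnc_id, e.mrna_id) for e, _ in trans}
        assert set(planted_in_modules) <= recovered
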