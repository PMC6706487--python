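"""Non-coding region extraction, homologous grouping, alignment and
nucleotide diversity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import feature, make_record
from plastokit.divergence import (
    align_group,
    diversity_scan,
    extract_noncoding,
    group_homologous,
    nucleotide_diversity,
    rank_hotspots,
)


def rand_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestExtractNoncoding:
    def test_single_igs_between_two_genes(self):
        seq = rand_seq(0, 400)
        rec = make_record(seq, [
            feature("gA", "CDS", "+", [(0, 100)]),
            feature("gB", "CDS", "+", [(350, 400)]),
        ])
        regions = extract_noncoding(rec, min_len=200)
        assert len(regions) == 1
        r = regions[0]
        assert (r.name, r.kind, r.span) == ("gA-gB", "IGS", (100, 350))
        assert r.sequence == seq[100:350]

    def test_length_filter_is_strict(self):
        seq = rand_seq(1, 350)
        rec = make_record(seq, [
            feature("gA", "CDS", "+", [(0, 100)]),
            feature("gB", "CDS", "+", [(300, 350)]),  # IGS exactly 200
        ])
        assert extract_noncoding(rec, min_len=200) == []

    def test_intron_region_from_two_part_gene(self):
        seq = rand_seq(2, 1200)
        rec = make_record(seq, [
            feature("gA", "CDS", "+", [(0, 100), (700, 800)]),
            feature("gB", "CDS", "+", [(900, 1200)]),
        ])
        regions = extract_noncoding(rec, min_len=200)
        names = {r.name: r for r in regions}
        assert "gA.intron1" in names
        assert names["gA.intron1"].span == (100, 700)
        assert names["gA.intron1"].kind == "intron"

    def test_circular_wrap_gap(self):
        seq = rand_seq(3, 1000)
        rec = make_record(seq, [
            feature("gA", "CDS", "+", [(200, 300)]),
            feature("gB", "CDS", "+", [(400, 500)]),
        ])
        regions = extract_noncoding(rec, min_len=200)
        wrap = [r for r in regions if r.name == "gB-gA"]
        assert len(wrap) == 1
        assert wrap[0].sequence == seq[500:] + seq[:200]


class TestGroupHomologous:
    def _regions(self, gid, names):
        return [
            r
            for name in names
            for r in extract_noncoding(
                make_record(
                    rand_seq(hash(gid) % 100, 700),
                    [
                        feature(name.split("-")[0], "CDS", "+", [(0, 100)]),
                        feature(name.split("-")[1], "CDS", "+", [(600, 700)]),
                    ],
                    rec_id=gid,
                ),
                min_len=200,
            )
        ]

    def test_presence_in_all_genomes_required(self):
        regs = {
            "g1": self._regions("g1", ["gA-gB"]),
            "g2": self._regions("g2", ["gA-gB"]),
            "g3": [],
        }
        groups, dropped = group_homologous(regs)
        assert groups == []
        assert dropped and "g3" in dropped[0]

    def test_name_order_normalized(self):
        regs = {
            "g1": self._regions("g1", ["gA-gB"]),
            "g2": self._regions("g2", ["gB-gA"]),
        }
        groups, _ = group_homologous(regs)
        assert len(groups) == 1
        assert set(groups[0].sequences) == {"g1", "g2"}


def brute_force_global_alignment(a, b, match=2, mismatch=-1, open_=-5, extend=-1):
    """Exhaustive optimal global alignment score over all alignments of two
    short strings (affine gaps, recursion with memoisation)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 diagonal, 1 gap in b (a consumed), 2 gap in a
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = extend if state == 1 else open_
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = extend if state == 2 else open_
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


class TestAlignGroup:
    def test_identical_sequences_align_gap_free(self):
        s = rand_seq(4, 120)
        aln = align_group({"a": s, "b": s, "c": s})
        assert all(v == s for v in aln.values())

    def test_single_gap_alignment(self):
        aln = align_group({"a": "ACGT", "b": "ACT"})
        assert len(aln["a"]) == len(aln["b"]) == 4
        matches = sum(
            x == y and x != "-" for x, y in zip(aln["a"], aln["b"])
        )
        assert matches == 3
        assert aln["b"].count("-") == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pairwise_score_is_optimal(self, seed):
        """The internal aligner's pairwise result reaches the brute-force
        optimal score on short strings."""
        from plastokit.divergence import _aligner

        rng = np.random.default_rng(seed)
        a = rand_seq(seed, int(rng.integers(4, 10)))
        b = rand_seq(seed + 100, int(rng.integers(4, 10)))
        got = _aligner().align(a, b).score
        assert got == brute_force_global_alignment(a, b)

    def test_alignment_at_least_longest_input(self):
        seqs = {"a": rand_seq(5, 90), "b": rand_seq(6, 100), "c": rand_seq(7, 95)}
        aln = align_group(seqs)
        assert len(set(map(len, aln.values()))) == 1
        assert len(aln["a"]) >= 100

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_group({"a": "ACGT", "b": ""})


def pi_oracle(rows):
    """Independent average pairwise difference with complete deletion."""
    used = [
        i
        for i in range(len(rows[0]))
        if all(r[i] not in "-N" for r in rows)
    ]
    total, npair = 0.0, 0
    for a, b in itertools.combinations(rows, 2):
        diff = sum(a[i] != b[i] for i in used)
        total += diff / len(used)
        npair += 1
    return total / npair


class TestNucleotideDiversity:
    def test_identical_sequences_pi_zero(self):
        pi, used = nucleotide_diversity(["ACGTACGT", "ACGTACGT"])
        assert pi == 0.0 and used == 8

    def test_one_difference_in_hundred_sites(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        pi, used = nucleotide_diversity([a, b])
        assert used == 100
        assert pi == pytest.approx(0.01)

    def test_gap_columns_completely_deleted(self):
        pi, used = nucleotide_diversity(["AC-GT", "ACCGT", "ACCGA"])
        assert used == 4

    def test_two_sequences_equal_p_distance(self):
        a, b = rand_seq(8, 200), rand_seq(9, 200)
        pi, used = nucleotide_diversity([a, b])
        p = sum(x != y for x, y in zip(a, b)) / 200
        assert pi == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        base = list(rand_seq(seed, 80))
        for _ in range(4):
            row = base.copy()
            for pos in rng.integers(0, 80, size=6):
                row[pos] = "ACGT-"[rng.integers(0, 5)]
            rows.append("".join(row))
        pi, _ = nucleotide_diversity(rows)
        assert pi == pytest.approx(pi_oracle(rows))

    @given(st.permutations(range(4)))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_invariant_under_sequence_order(self, perm):
        rows = [rand_seq(i, 60) for i in range(4)]
        a, _ = nucleotide_diversity(rows)
        b, _ = nucleotide_diversity([rows[i] for i in perm])
        assert a == pytest.approx(b)

    def test_all_gap_columns_undefined(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["--", "A-"])


class TestRankHotspots:
    def test_k_zero_returns_empty(self, small_genus):
        records, _ = small_genus
        results, _ = diversity_scan(records)
        top, _ = rank_hotspots(results, k=0)
        assert top == []

    def test_planted_hotspots_occupy_top_ranks(self, small_genus):
        records, manifest = small_genus
        results, _ = diversity_scan(records)
        k = len(manifest.hotspot_truth)
        top, high = rank_hotspots(results, k=k)

        def norm(name):
            return tuple(sorted(name.split("-")))

        assert {norm(t.name) for t in top} == {
            norm(h["name"]) for h in manifest.hotspot_truth
        }
        assert all(t.pi > 0.01 for t in top)

    def test_identical_genomes_rank_by_name(self, small_genus):
        records, _ = small_genus
        first = next(iter(records.values()))
        clones = {"c1": first, "c2": first}
        results, _ = diversity_scan(clones)
        top, high = rank_hotspots(results, k=5)
        assert all(r.pi == 0 for r in results)
        assert high == []
        assert [t.name for t in top] == sorted(t.name for t in top)

    def test_background_pi_matches_star_phylogeny_expectation(self, small_genus):
        """Mean Pi of non-hotspot spacers approaches 2*theta - 4/3*theta^2
        for the background substitution probability theta."""
        records, manifest = small_genus
        results, _ = diversity_scan(records)
        hot = {tuple(sorted(h["name"].split("-"))) for h in manifest.hotspot_truth}
        background = [
            r.pi
            for r in results
            if tuple(sorted(r.name.split("-"))) not in hot and r.region.kind == "IGS"
        ]
        theta = manifest.rates["background"]
        expected = 2 * theta - 4 / 3 * theta**2
        assert np.mean(background) == pytest.approx(expected, rel=0.35)
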