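"""Microsatellite detection, canonical labels, compound merging, genomic
context and cross-genome polymorphism."""

import re

import numpy as np
import pytest

from conftest import feature, make_record
from plastokit.plastome_io import reverse_complement
from plastokit.ssr import (
    CompoundSSR,
    DEFAULT_THRESHOLDS,
    SSRLocus,
    canonical_motif,
    classify_polymorphic,
    find_ssrs,
    is_primitive,
    locate_ssr,
    merge_compound,
)


def regex_ssr_oracle(seq, thresholds=DEFAULT_THRESHOLDS):
    """Brute-force regex-style scan: maximal perfect repeats of primitive
    1-6 bp units meeting the thresholds, shortest unit wins on containment."""
    found = []
    for u in sorted(thresholds):
        pattern = re.compile(r"(.{%d})\1{%d,}" % (u, thresholds[u] - 1))
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if not m:
                break
            motif = m.group(1)
            n_rep = (m.end() - m.start()) // u
            span = (m.start(), m.start() + u * n_rep)
            if is_primitive(motif):
                if not any(
                    ks <= span[0] and span[1] <= ke for ks, ke, _ in found
                ):
                    found.append((span[0], span[1], motif))
            pos = m.start() + 1
        found.sort()
    return {(s, e) for s, e, _ in found}


def rand_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestFindSsrs:
    def test_mononucleotide_at_threshold(self):
        seq = "GCGCGTAC" + "A" * 10 + "GTCAGCTA"
        (locus,) = find_ssrs(seq)
        assert locus.motif == "A"
        assert locus.n_repeats == 10
        assert locus.span == (8, 18)

    def test_below_threshold_not_reported(self):
        assert find_ssrs("GCGCGTAC" + "A" * 9 + "GTCAGCTA") == []

    @pytest.mark.parametrize(
        "motif,reps", [("AG", 5), ("AAG", 4), ("AAAT", 3), ("AATCT", 3), ("AATTCG", 3)]
    )
    def test_each_unit_length_threshold(self, motif, reps):
        # guard bases stop the run from extending into the flanks
        gl = next(b for b in "CGTA" if b != motif[-1])
        gr = next(b for b in "CGTA" if b != motif[0])
        seq = "GCCGGTC" + gl + motif * reps + gr + "AGTCGGC"
        loci = find_ssrs(seq)
        assert any(l.motif == motif and l.n_repeats == reps for l in loci)

    def test_non_primitive_unit_not_duplicated(self):
        """An (AT)6 run is one dinucleotide locus, not also an (ATAT) one."""
        seq = "GCCGG" + "AT" * 6 + "CGGCC"
        loci = find_ssrs(seq)
        assert len(loci) == 1
        assert loci[0].unit_len == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_regex_oracle_on_random_kb(self, seed):
        seq = rand_seq(seed, 1000)
        got = {l.span for l in find_ssrs(seq)}
        assert got == regex_ssr_oracle(seq)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_locus_revalidates(self, seed):
        seq = rand_seq(seed, 2000) + "TTTTTTTTTTT" + rand_seq(seed + 50, 100)
        for l in find_ssrs(seq):
            s, e = l.span
            assert seq[s:e] == l.motif * l.n_repeats
            assert l.n_repeats >= DEFAULT_THRESHOLDS[l.unit_len]

    @pytest.mark.parametrize("seed", [3, 4])
    def test_strand_symmetry_of_canonical_classes(self, seed):
        def strand_class(motif):
            rots = lambda m: {m[i:] + m[:i] for i in range(len(m))}
            return min(rots(motif) | rots(reverse_complement(motif)))

        seq = rand_seq(seed, 1500) + "A" * 12 + "GC" + "AATCT" * 4 + rand_seq(seed + 9, 200)
        fwd = sorted((strand_class(l.motif), l.length) for l in find_ssrs(seq))
        rev = sorted(
            (strand_class(l.motif), l.length)
            for l in find_ssrs(reverse_complement(seq))
        )
        assert fwd == rev


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,label",
        [
            ("C", "C/G"),
            ("AGCTAT", "AGCTAT/AGCTAT"),
            ("AT", "AT/AT"),
            ("AATCT", "AATCT/AGATT"),
            ("AATTC", "AATTC/AATTG"),
        ],
    )
    def test_known_labels(self, motif, label):
        assert canonical_motif(motif) == label

    def test_non_primitive_is_error(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")


class TestMergeCompound:
    def _locus(self, motif, reps, start):
        return SSRLocus(motif=motif, n_repeats=reps,
                        span=(start, start + len(motif) * reps))

    def test_adjacent_loci_fuse_with_semicolon(self):
        a = self._locus("AAAT", 3, 100)
        b = self._locus("ATT", 4, 112)
        (compound,) = merge_compound([a, b])
        assert isinstance(compound, CompoundSSR)
        assert compound.label == "(AAAT)3;(ATT)4"
        assert compound.span == (100, 124)

    def test_gap_recorded_in_label(self):
        a = self._locus("T", 10, 0)
        b = self._locus("TTAGA", 3, 16)
        (compound,) = merge_compound([a, b])
        assert compound.label == "(T)106n(TTAGA)3"

    def test_distant_loci_not_merged(self):
        a = self._locus("A", 10, 0)
        b = self._locus("T", 10, 210)
        out = merge_compound([a, b], max_gap=100)
        assert len(out) == 2
        assert all(isinstance(l, SSRLocus) for l in out)


class TestLocateSsr:
    def _record(self):
        seq = rand_seq(42, 1000)
        feats = [
            feature("rpl32", "CDS", "+", [(100, 250)]),
            feature("twoPart", "CDS", "+", [(300, 360), (500, 560)]),
            feature("ndhF", "CDS", "-", [(700, 900)]),
        ]
        return make_record(seq, feats)

    def test_inside_cds(self):
        locus = SSRLocus("TTC", 4, (120, 132))
        assert locate_ssr(locus, self._record()).location_class == "CDS"

    def test_inside_intron(self):
        locus = SSRLocus("T", 10, (400, 410))
        located = locate_ssr(locus, self._record())
        assert located.location_class == "Intron"
        assert located.context == ("twoPart", "twoPart")

    def test_intergenic_with_flanks(self):
        locus = SSRLocus("A", 10, (600, 610))
        located = locate_ssr(locus, self._record())
        assert located.location_class == "IGS"
        assert located.context == ("twoPart", "ndhF")

    def test_unannotated_record_is_igs(self):
        rec = make_record(rand_seq(1, 500))
        located = locate_ssr(SSRLocus("A", 10, (10, 20)), rec)
        assert located.location_class == "IGS"


class TestClassifyPolymorphic:
    def _genomes(self, counts=(10, 12, 11)):
        """Three genomes sharing one T-run at homologous flanks."""
        flank_l = rand_seq(5, 300) + "C"  # guards: the run cannot extend
        flank_r = "G" + rand_seq(6, 300)
        records, per_genome = {}, {}
        for i, c in enumerate(counts):
            gid = f"g{i}"
            seq = flank_l + "T" * c + flank_r
            rec = make_record(seq, rec_id=gid)
            records[gid] = rec
            per_genome[gid] = find_ssrs(seq, genome_id=gid)
        return per_genome, records

    def test_planted_variable_locus_is_polymorphic(self):
        per_genome, records = self._genomes((10, 12, 11))
        result = classify_polymorphic(per_genome, records)
        assert len(result.polymorphic) == 1
        grp = result.polymorphic[0]
        assert grp.variable
        assert {l.length for l in grp.loci.values()} == {10, 12, 11}

    def test_identical_locus_is_monomorphic(self):
        per_genome, records = self._genomes((10, 10, 10))
        result = classify_polymorphic(per_genome, records)
        assert result.polymorphic == []
        assert len(result.monomorphic) == 1

    def test_locus_missing_from_one_genome_is_partial(self):
        per_genome, records = self._genomes((10, 12, 11))
        per_genome["g2"] = []
        result = classify_polymorphic(per_genome, records)
        assert result.polymorphic == []
        assert len(result.partial) == 1

    def test_needs_two_genomes(self):
        per_genome, records = self._genomes()
        with pytest.raises(ValueError):
            classify_polymorphic(
                {"g0": per_genome["g0"]}, {"g0": records["g0"]}
            )

    def test_planted_panel_recovered_exactly(self, small_genus):
        """On the simulated genus, the polymorphic set equals the planted
        polymorphic panel with precision and recall 1."""
        records, manifest = small_genus
        per_genome = {}
        for gid, rec in records.items():
            loci = merge_compound(find_ssrs(rec.sequence, genome_id=gid))
            per_genome[gid] = [locate_ssr(l, rec) for l in loci]
        result = classify_polymorphic(per_genome, records)
        truth_ids = manifest.polymorphic_ids()
        assert len(result.polymorphic) == len(truth_ids)
        truth_spans = {
            tuple(t["full_span"][gid])
            for t in manifest.ssr_truth
            if t["polymorphic"]
            for gid in records
        }
        got_spans = {
            l.span for grp in result.polymorphic for l in grp.loci.values()
        }
        assert got_spans == truth_spans
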