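"""Quadripartite architecture of plastomes.

Land-plant plastomes carry two large inverted repeats (IRa/IRb) separating a
large and a small single-copy region (LSC/SSC). This module locates the IR
pair from sequence alone (seed-and-extend against the reverse complement),
partitions the circle into LSC-IRb-SSC-IRa, summarises gene content and
characterises the four junctions JLB, JSB, JSA and JLA — the places where IR
expansion/contraction shows up between species.

Junction positions are 0-based indices of the first base of the downstream
region, so gap/overlap arithmetic with half-open feature intervals is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .plastome_io import (
    GeneFeature,
    PlastomeRecord,
    extract_feature_sequence,
    gc_fraction,
    reverse_complement,
)

__all__ = [
    "QuadripartitePartition",
    "GeneInventory",
    "JunctionReport",
    "detect_inverted_repeat",
    "partition",
    "gene_inventory",
    "junction_report",
    "region_stats",
]

JUNCTION_ORDER = ("JLB", "JSB", "JSA", "JLA")

#: DNA codon -> amino acid under the bacterial/plastid genetic code (NCBI 11)
_PLASTID_TABLE_ID = 11

#: inter-part distance beyond which a multi-part gene is treated as
#: trans-spliced rather than intron-containing (rps12 in practice)
TRANS_SPLICE_GAP = 20_000


# ---------------------------------------------------------------------------
# Inverted repeat detection
# ---------------------------------------------------------------------------

def detect_inverted_repeat(
    seq: str,
    min_len: int = 10_000,
    max_mismatch: int = 0,
    k: int = 25,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Find the longest pair of disjoint reverse-complementary intervals.

    k-mer seeds are matched between the sequence and its reverse complement
    and extended without gaps, spending at most ``max_mismatch``
    substitutions. Returns the two intervals ordered by start position, or
    ``None`` when nothing of at least ``min_len`` exists. Ties on length are
    broken by the leftmost start.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    rc = reverse_complement(seq)

    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        index.setdefault(rc[j : j + k], []).append(j)

    best: tuple[int, int, int] | None = None  # (length, a_start, b_start)
    covered: dict[int, int] = {}  # diagonal -> rightmost i already extended

    for i in range(n - k + 1):
        hits = index.get(seq[i : i + k])
        if not hits:
            continue
        for j in hits:
            d = i - j
            if covered.get(d, -1) >= i + k:
                continue
            i0, j0, i1, j1 = i, j, i + k, j + k
            # exact extension first
            while i0 > 0 and j0 > 0 and seq[i0 - 1] == rc[j0 - 1]:
                i0 -= 1
                j0 -= 1
            while i1 < n and j1 < n and seq[i1] == rc[j1]:
                i1 += 1
                j1 += 1
            budget = max_mismatch
            while budget > 0:
                # greedily spend one substitution on whichever side regains
                # the longer exact run
                li = lj = i0 - 1, j0 - 1
                gain_left = 0
                if i0 > 1 and j0 > 1:
                    a, b = i0 - 2, j0 - 2
                    while a >= 0 and b >= 0 and seq[a] == rc[b]:
                        a -= 1
                        b -= 1
                        gain_left += 1
                gain_right = 0
                if i1 + 1 < n and j1 + 1 < n:
                    a, b = i1 + 1, j1 + 1
                    while a < n and b < n and seq[a] == rc[b]:
                        a += 1
                        b += 1
                        gain_right += 1
                if gain_left == 0 and gain_right == 0:
                    break
                if gain_left >= gain_right:
                    i0 -= 1 + gain_left
                    j0 -= 1 + gain_left
                else:
                    i1 += 1 + gain_right
                    j1 += 1 + gain_right
                budget -= 1
            covered[d] = max(covered.get(d, -1), i1)
            length = i1 - i0
            if length < min_len:
                continue
            # rc[j0:j1] is seq[n-j1:n-j0] reverse-complemented
            a = (i0, i1)
            b = (n - j1, n - j0)
            if a > b:
                a, b = b, a
            if a[1] > b[0]:  # overlapping (palindrome through centre)
                continue
            cand = (length, a[0], b[0])
            if best is None or length > best[0] or (
                length == best[0] and (a[0], b[0]) < (best[1], best[2])
            ):
                best = cand
    if best is None:
        return None
    length, a0, b0 = best
    return (a0, a0 + length), (b0, b0 + length)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the linearized circle.

    Intervals are ``(start, end)`` with ``end`` possibly exceeding the genome
    length for the region that wraps across the origin. ``junctions`` maps
    JLB/JSB/JSA/JLA to the index of the first base of the downstream region.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    junctions: dict[str, int] = field(default_factory=dict)

    def length(self, region: str) -> int:
        s, e = getattr(self, region.lower())
        return e - s

    @property
    def region_lengths(self) -> dict[str, int]:
        return {r: self.length(r) for r in ("lsc", "irb", "ssc", "ira")}

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(self, name)
            if s <= pos < e or s <= pos + self.genome_length < e:
                return name.upper()
        raise ValueError(f"position {pos} not covered")  # pragma: no cover

    def bases_in_region(self, interval: tuple[int, int], region: str) -> int:
        """Bases of a (possibly wrapping) interval inside one region."""
        s, e = interval
        n = self.genome_length
        if s > e:
            e += n
        rs, re = getattr(self, region.lower())
        total = 0
        for shift in (-n, 0, n):
            lo = max(s + shift, rs)
            hi = min(e + shift, re)
            if hi > lo:
                total += hi - lo
        return total


def partition(
    record: PlastomeRecord,
    ir: tuple[tuple[int, int], tuple[int, int]],
) -> QuadripartitePartition:
    """Partition the circle given the detected IR pair.

    The longer of the two arcs between the IR copies becomes the LSC; IRb is
    the IR copy immediately downstream of the LSC in the record orientation.
    """
    (s1, e1), (s2, e2) = sorted(ir)
    n = record.length
    if e1 > s2 or e2 > n + s1:
        raise ValueError("IR intervals are not disjoint on the circle")
    arc_a = (e1, s2)  # between copy1 and copy2
    arc_b = (e2, n + s1)  # wraps through the origin
    len_a, len_b = s2 - e1, n + s1 - e2
    if len_a == 0 or len_b == 0:
        raise ValueError("IR intervals leave no room for single-copy regions")
    if len_a == len_b:
        warnings.warn(
            "single-copy arcs have equal length; taking the arc after the "
            "first IR copy as LSC by orientation convention"
        )
    if len_a >= len_b:
        lsc, ssc = arc_a, arc_b
        irb, ira = (s2, e2), (s1, e1)
    else:
        lsc, ssc = arc_b, arc_a
        irb, ira = (s1, e1), (s2, e2)
    junctions = {
        "JLB": irb[0] % n,
        "JSB": ssc[0] % n,
        "JSA": ira[0] % n,
        "JLA": lsc[0] % n,
    }
    return QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n, junctions=junctions
    )


def region_stats(record: PlastomeRecord, part: QuadripartitePartition) -> pd.DataFrame:
    """Per-region length and GC table (plus the whole genome)."""
    rows = []
    n = record.length
    for name in ("lsc", "irb", "ssc", "ira"):
        s, e = getattr(part, name)
        seq = (
            record.sequence[s % n :] + record.sequence[: e % n]
            if e > n
            else record.sequence[s:e]
        )
        rows.append(
            {
                "region": name.upper(),
                "start": s % n,
                "end": e % n if e > n else e,
                "length": e - s,
                "gc": round(gc_fraction(seq), 4),
            }
        )
    rows.append(
        {
            "region": "genome",
            "start": 0,
            "end": n,
            "length": n,
            "gc": round(gc_fraction(record.sequence), 4),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene inventory
# ---------------------------------------------------------------------------

@dataclass
class GeneInventory:
    n_unique_genes: int
    n_pcg: int
    n_trna: int
    n_rrna: int
    duplicated_in_ir: dict[str, list[str]]
    intron_bearing: dict[str, int]  # gene -> intron count
    trans_spliced: list[str]
    alternative_starts: dict[str, str]  # gene -> first codon (RNA alphabet)
    warnings: list[str] = field(default_factory=list)

    @property
    def duplicated_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.duplicated_in_ir.items()}


_KIND_CLASS = {"CDS": "pcg", "tRNA": "trna", "rRNA": "rrna"}


def _is_trans_spliced(feature: GeneFeature) -> bool:
    parts = sorted(feature.parts)
    return any(b[0] - a[1] > TRANS_SPLICE_GAP for a, b in zip(parts, parts[1:]))


def gene_inventory(
    record: PlastomeRecord,
    part: QuadripartitePartition | None = None,
) -> GeneInventory:
    """Summarise gene content: unique genes per class, IR duplicates,
    intron-bearing and trans-spliced genes, non-AUG start codons.

    Genes are identified by their symbol (tRNA anticodon suffix retained);
    a gene counts as duplicated-in-IR when two same-symbol features lie, by
    majority of their length, in different IR copies.
    """
    notes: list[str] = []
    by_class: dict[str, dict[str, list[GeneFeature]]] = {
        "pcg": {},
        "trna": {},
        "rrna": {},
    }
    for f in record.features:
        cls = _KIND_CLASS.get(f.kind)
        if cls is None:
            continue
        by_class[cls].setdefault(f.name, []).append(f)

    duplicated: dict[str, list[str]] = {"pcg": [], "trna": [], "rrna": []}
    if part is not None:
        for cls, genes in by_class.items():
            for name, feats in genes.items():
                if len(feats) < 2:
                    continue
                regions = set()
                for f in feats:
                    in_irb = sum(part.bases_in_region(p, "irb") for p in f.parts)
                    in_ira = sum(part.bases_in_region(p, "ira") for p in f.parts)
                    half = f.span_length() / 2
                    if in_irb > half:
                        regions.add("irb")
                    elif in_ira > half:
                        regions.add("ira")
                if {"irb", "ira"} <= regions:
                    duplicated[cls].append(name)
            duplicated[cls].sort()

    intron_bearing: dict[str, int] = {}
    trans_spliced: list[str] = []
    for genes in by_class.values():
        for name, feats in genes.items():
            f = max(feats, key=lambda f: len(f.parts))
            if len(f.parts) < 2:
                continue
            if _is_trans_spliced(f):
                trans_spliced.append(name)
            else:
                intron_bearing[name] = f.n_introns
    trans_spliced.sort()

    alternative_starts: dict[str, str] = {}
    for name, feats in by_class["pcg"].items():
        cds = extract_feature_sequence(record, feats[0])
        if len(cds) % 3 != 0:
            notes.append(f"{name}: CDS length {len(cds)} not divisible by 3")
        if len(cds) >= 3:
            start = cds[:3]
            if start != "ATG":
                alternative_starts[name] = start.replace("T", "U")

    n_pcg = len(by_class["pcg"])
    n_trna = len(by_class["trna"])
    n_rrna = len(by_class["rrna"])
    return GeneInventory(
        n_unique_genes=n_pcg + n_trna + n_rrna,
        n_pcg=n_pcg,
        n_trna=n_trna,
        n_rrna=n_rrna,
        duplicated_in_ir=duplicated,
        intron_bearing=dict(sorted(intron_bearing.items())),
        trans_spliced=trans_spliced,
        alternative_starts=dict(sorted(alternative_starts.items())),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Junction report
# ---------------------------------------------------------------------------

@dataclass
class JunctionEntry:
    junction: str
    side: str  # 'upstream' | 'downstream'
    gene: str
    signed_distance: int  # positive gap; negative = bases across the junction


@dataclass
class JunctionReport:
    entries: list[JunctionEntry]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "junction": e.junction,
                    "gene": e.gene,
                    "side": e.side,
                    "signed_distance": e.signed_distance,
                }
                for e in self.entries
            ]
        )

    def get(self, junction: str, side: str) -> JunctionEntry | None:
        for e in self.entries:
            if e.junction == junction and e.side == side:
                return e
        return None


def _feature_span(f: GeneFeature, n: int) -> tuple[int, int]:
    if f.wraps_origin:
        # single logical span crossing the origin
        return (f.parts[0][0], f.parts[-1][1] + n)
    return (f.start, f.end)


def junction_report(
    record: PlastomeRecord,
    part: QuadripartitePartition,
) -> JunctionReport:
    """Nearest annotated gene on each side of each junction, with the signed
    distance of its closest end: positive = gap before the junction,
    negative = the gene runs across the junction by that many bases (for a
    gene crossing JLB this is the length of its pseudogenised IRa copy).
    """
    n = record.length
    feats = [
        f for f in record.features if f.kind in ("CDS", "tRNA", "rRNA")
    ]
    if not feats:
        return JunctionReport(entries=[], warnings=["record has no annotated genes"])

    entries: list[JunctionEntry] = []
    for name in JUNCTION_ORDER:
        p = part.junctions[name]
        up_best = None  # (dist_from_start, feature)
        down_best = None
        for f in feats:
            s, e = _feature_span(f, n)
            span = e - s
            up_key = (p - s) % n
            if up_key == 0:
                up_key = n
            down_key = (s - p) % n
            if up_best is None or (up_key, f.name) < up_best[:2]:
                up_best = (up_key, f.name, f, s, e, span)
            if down_best is None or (down_key, f.name) < down_best[:2]:
                down_best = (down_key, f.name, f, s, e, span)
        up_key, _, fu, su, eu, span_u = up_best
        offset = (p - su) % n
        if offset < span_u:  # gene extends across the junction
            dist_u = -(span_u - offset)
        else:
            dist_u = (p - eu) % n
        entries.append(JunctionEntry(name, "upstream", fu.name, dist_u))
        down_key, _, fd, sd, ed, span_d = down_best
        entries.append(JunctionEntry(name, "downstream", fd.name, down_key))
    return JunctionReport(entries=entries)
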