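"""Non-coding divergence scanning: extract intergenic spacers and introns,
group homologues across genomes, align them and rank nucleotide-diversity
(Pi) hotspots.

Pi follows Nei's average pairwise proportion of differing sites. Columns
with a gap (or N) in any sequence are excluded before counting — complete
deletion, the default of the DNA polymorphism software this mirrors — so
Pi is a pure substitution measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align

from .plastome_io import GeneFeature, PlastomeRecord

__all__ = [
    "NonCodingRegion",
    "RegionGroup",
    "DiversityResult",
    "extract_noncoding",
    "group_homologous",
    "align_group",
    "nucleotide_diversity",
    "rank_hotspots",
    "diversity_scan",
]

#: inter-part distance beyond which parts are separate blocks (trans-splicing)
_TRANS_GAP = 20_000


@dataclass
class NonCodingRegion:
    """One non-coding interval of one genome."""

    name: str  # "geneA-geneB" for IGS, "gene.intronK" for introns
    kind: str  # "IGS" | "intron"
    span: tuple[int, int]
    sequence: str
    genome_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def group_key(self) -> tuple:
        if self.kind == "IGS":
            a, b = self.name.split("-", 1) if "-" in self.name else (self.name, "")
            copy = ""
            if "#" in b:
                b, copy = b.split("#")
            return ("IGS", tuple(sorted((a, b))), copy)
        return ("intron", self.name)


@dataclass
class RegionGroup:
    """Homologous non-coding regions across genomes, keyed by name."""

    name: str
    kind: str
    sequences: dict[str, str]  # genome id -> sequence
    spans: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class DiversityResult:
    region: RegionGroup
    alignment: dict[str, str]  # genome id -> padded sequence
    pi: float
    n_sequences: int
    sites_used: int

    @property
    def name(self) -> str:
        return self.region.name


def _gene_blocks(record: PlastomeRecord) -> list[tuple[int, int, str]]:
    """(start, end, name) blocks covering genic sequence; trans-spliced
    genes contribute one block per distant exon cluster."""
    blocks = []
    for f in record.features_of_kind("CDS", "tRNA", "rRNA"):
        parts = sorted(f.parts)
        cur = [parts[0]]
        for prev, nxt in zip(parts, parts[1:]):
            if nxt[0] - prev[1] > _TRANS_GAP:
                blocks.append((cur[0][0], cur[-1][1], f.name))
                cur = [nxt]
            else:
                cur.append(nxt)
        blocks.append((cur[0][0], cur[-1][1], f.name))
    return sorted(blocks)


def extract_noncoding(
    record: PlastomeRecord, min_len: int = 200
) -> list[NonCodingRegion]:
    """IGS and intron regions strictly longer than ``min_len``.

    IGS regions are the maximal intervals not covered by any gene block,
    named after the flanking genes; introns are inter-part gaps of
    multi-part genes, named gene.intronK. Names that recur within one
    genome (IR duplicates) get a ``#2``-style suffix in coordinate order.
    """
    regions: list[NonCodingRegion] = []
    seq = record.sequence
    n = record.length

    for f in record.features_of_kind("CDS", "tRNA", "rRNA"):
        parts = sorted(f.parts)
        k = 0
        for prev, nxt in zip(parts, parts[1:]):
            gap = nxt[0] - prev[1]
            if gap > _TRANS_GAP:
                continue
            k += 1
            if gap > min_len:
                regions.append(
                    NonCodingRegion(
                        name=f"{f.name}.intron{k}",
                        kind="intron",
                        span=(prev[1], nxt[0]),
                        sequence=seq[prev[1] : nxt[0]],
                        genome_id=record.id,
                    )
                )

    blocks = _gene_blocks(record)
    if blocks:
        # coverage clusters [start, end, first_gene, last_gene]
        clusters: list[list] = []
        for s, e, name in blocks:
            if clusters and s <= clusters[-1][1]:
                if e >= clusters[-1][1]:
                    clusters[-1][1] = e
                    clusters[-1][3] = name
            else:
                clusters.append([s, e, name, name])
        m = len(clusters)
        for i in range(m):
            _, ce, _, left_gene = clusters[i]
            ns, _, right_gene, _ = clusters[(i + 1) % m]
            wraps = i + 1 >= m
            gap_end = ns + n if wraps else ns
            if wraps and not record.circular:
                continue
            if gap_end - ce > min_len:
                segment = seq[ce:] + seq[:ns] if wraps else seq[ce:gap_end]
                regions.append(
                    NonCodingRegion(
                        name=f"{left_gene}-{right_gene}",
                        kind="IGS",
                        span=(ce % n, ns),
                        sequence=segment,
                        genome_id=record.id,
                    )
                )

    # suffix duplicate names in coordinate order
    seen: dict[str, int] = {}
    regions.sort(key=lambda r: r.span)
    for r in regions:
        c = seen.get(r.name, 0)
        seen[r.name] = c + 1
        if c:
            r.name = f"{r.name}#{c + 1}"
    return regions


def group_homologous(
    regions: dict[str, list[NonCodingRegion]],
) -> tuple[list[RegionGroup], list[str]]:
    """Group regions by normalized name; keep groups present in every genome.

    IGS names are order-normalized (A-B == B-A). Returns the retained
    groups and log messages for the dropped ones.
    """
    genomes = list(regions)
    table: dict[tuple, dict[str, NonCodingRegion]] = {}
    for g in genomes:
        for r in regions[g]:
            table.setdefault(r.group_key, {})[g] = r
    groups: list[RegionGroup] = []
    dropped: list[str] = []
    for key, members in sorted(table.items(), key=lambda kv: str(kv[0])):
        if len(members) < len(genomes):
            missing = sorted(set(genomes) - set(members))
            name = next(iter(members.values())).name
            dropped.append(f"{name}: absent from {', '.join(missing)}")
            continue
        first = members[genomes[0]]
        groups.append(
            RegionGroup(
                name=first.name,
                kind=first.kind,
                sequences={g: members[g].sequence for g in genomes},
                spans={g: members[g].span for g in genomes},
            )
        )
    return groups, dropped


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def _pairwise(a: str, b: str) -> tuple[str, str]:
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_group(seqs: dict[str, str]) -> dict[str, str]:
    """Deterministic star-progressive alignment around the first sequence.

    Every sequence is globally aligned to the first (match +2, mismatch -1,
    gap open -5, gap extend -1); insertions relative to the reference are
    merged into a shared gap pattern, joining sequences in order of
    decreasing pairwise identity to the reference.
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    if any(not s for s in seqs.values()):
        raise ValueError("empty sequence in group")
    keys = list(seqs)
    ref_key = keys[0]
    ref = seqs[ref_key]

    pair: dict[str, tuple[str, str]] = {}
    ident: dict[str, float] = {}
    for g in keys[1:]:
        ra, sa = _pairwise(ref, seqs[g])
        pair[g] = (ra, sa)
        matches = sum(x == y and x != "-" for x, y in zip(ra, sa))
        ident[g] = matches / len(ra)
    order = sorted(keys[1:], key=lambda g: (-ident[g], keys.index(g)))

    # insertion length before each reference boundary (0..len(ref))
    max_ins = [0] * (len(ref) + 1)
    ins_per_seq: dict[str, list[int]] = {}
    for g in order:
        ra, _ = pair[g]
        ins = [0] * (len(ref) + 1)
        pos = 0
        for ch in ra:
            if ch == "-":
                ins[pos] += 1
            else:
                pos += 1
        ins_per_seq[g] = ins
        for i, v in enumerate(ins):
            max_ins[i] = max(max_ins[i], v)

    def expand(aligned_ref: str, aligned_seq: str, ins: list[int]) -> str:
        pos = 0
        chunks = {i: [] for i in range(len(ref) + 1)}
        buf = []
        for r_ch, s_ch in zip(aligned_ref, aligned_seq):
            if r_ch == "-":
                buf.append(s_ch)
            else:
                chunks[pos].append(("ins", buf))
                buf = []
                chunks[pos].append(("base", s_ch))
                pos += 1
        chunks[pos].append(("ins", buf))
        res = []
        pos = 0
        for i in range(len(ref) + 1):
            inserted = []
            base = None
            for tag, val in chunks.get(i, []):
                if tag == "ins":
                    inserted = val
                else:
                    base = val
            res.append("".join(inserted) + "-" * (max_ins[i] - len(inserted)))
            if base is not None:
                res.append(base)
        return "".join(res)

    out: dict[str, str] = {}
    ref_aln = []
    for i in range(len(ref)):
        ref_aln.append("-" * max_ins[i])
        ref_aln.append(ref[i])
    ref_aln.append("-" * max_ins[len(ref)])
    out[ref_key] = "".join(ref_aln)
    for g in order:
        ra, sa = pair[g]
        out[g] = expand(ra, sa, ins_per_seq[g])
    # restore input order
    out = {g: out[g] for g in keys}
    lengths = {len(v) for v in out.values()}
    assert len(lengths) == 1, "star merge produced ragged alignment"
    return out


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(alignment) -> tuple[float, int]:
    """Nei's Pi with complete deletion of gap/N columns.

    ``alignment`` is a dict or list of equal-length strings. Returns
    ``(pi, sites_used)``; raises when no ungapped site remains.
    """
    rows = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(rows) < 2:
        raise ValueError("Pi needs at least two sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    mat = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    good = ~((mat == b"-") | (mat == b"N")).any(axis=0)
    used = int(good.sum())
    if used == 0:
        raise ValueError("Pi undefined: no gap-free sites")
    sub = mat[:, good]
    total = 0.0
    npair = 0
    for i, j in combinations(range(len(rows)), 2):
        total += (sub[i] != sub[j]).sum() / used
        npair += 1
    return total / npair, used


def rank_hotspots(
    results: list[DiversityResult], k: int = 10, pi_cutoff: float = 0.01
) -> tuple[list[DiversityResult], list[DiversityResult]]:
    """Top-k regions by Pi (ties by name) and the subset with Pi > cutoff."""
    ranked = sorted(results, key=lambda r: (-r.pi, r.name))
    return ranked[:k], [r for r in ranked if r.pi > pi_cutoff]


def diversity_scan(
    records: dict[str, PlastomeRecord], min_len: int = 200
) -> tuple[list[DiversityResult], list[str]]:
    """Full non-coding Pi scan over a set of annotated genomes."""
    regions = {g: extract_noncoding(r, min_len) for g, r in records.items()}
    groups, log = group_homologous(regions)
    results: list[DiversityResult] = []
    for grp in groups:
        if len(set(grp.sequences.values())) == 1:
            first = next(iter(grp.sequences.values()))
            aln = dict(grp.sequences)
            pi, used = 0.0, len(first)
        else:
            aln = align_group(grp.sequences)
            try:
                pi, used = nucleotide_diversity(aln)
            except ValueError as exc:
                log.append(f"{grp.name}: {exc}")
                continue
        results.append(
            DiversityResult(
                region=grp,
                alignment=aln,
                pi=pi,
                n_sequences=len(aln),
                sites_used=used,
            )
        )
    return results, log


def hotspot_frame(results: list[DiversityResult], k: int = 10) -> pd.DataFrame:
    """Tabular hotspot report: region, kind, length range, Pi, rank."""
    ranked = sorted(results, key=lambda r: (-r.pi, r.name))
    rows = []
    for rank, r in enumerate(ranked, 1):
        lens = [len(s) for s in r.region.sequences.values()]
        rows.append(
            {
                "region": r.name,
                "kind": r.region.kind,
                "length_min": min(lens),
                "length_max": max(lens),
                "n_genomes": r.n_sequences,
                "sites_used": r.sites_used,
                "pi": round(r.pi, 5),
                "rank": rank,
                "top_k": rank <= k,
            }
        )
    return pd.DataFrame(rows)
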