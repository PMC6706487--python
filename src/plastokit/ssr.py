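"""Microsatellite (cpSSR) mining and cross-genome polymorphism calling.

Detection follows the MISA conventions for perfect repeats: a locus is a
maximal, non-extendable run of a primitive 1-6 bp motif whose full-repeat
count meets a per-unit-length threshold (defaults: 10 for mononucleotides,
5 for di-, 4 for tri- and 3 for tetra-/penta-/hexanucleotides). Nearby loci
merge into compound SSRs. Polymorphism across the genomes of a genus is
called by anchoring each locus on its flanking sequence: loci whose flanks
match in every genome form a homologous group, and the group is polymorphic
when any genome differs in span length or motif composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .plastome_io import PlastomeRecord, reverse_complement

__all__ = [
    "SSRLocus",
    "CompoundSSR",
    "SSRGroup",
    "PolymorphismResult",
    "DEFAULT_THRESHOLDS",
    "find_ssrs",
    "canonical_motif",
    "is_primitive",
    "merge_compound",
    "locate_ssr",
    "classify_polymorphic",
    "motif_summary",
]

#: unit length -> minimum number of repeats
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

#: MISA's default maximum interruption between the motifs of a compound SSR
DEFAULT_COMPOUND_GAP = 100

#: maximum inter-part gap still treated as an intron when locating an SSR
_INTRON_GAP_LIMIT = 20_000


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Strand-symmetric class label "motif/revcomp-rotation".

    The second half is the lexicographically smallest rotation of the
    motif's reverse complement, so that e.g. AATCT -> "AATCT/AGATT",
    C -> "C/G" and AT -> "AT/AT".
    """
    if not motif or not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    best = min(rc[i:] + rc[:i] for i in range(len(rc)))
    return f"{motif}/{best}"


@dataclass
class SSRLocus:
    """One perfect microsatellite run."""

    motif: str
    n_repeats: int
    span: tuple[int, int]  # [start, end), end - start == len(motif)*n_repeats
    location_class: str | None = None  # CDS | Intron | IGS
    context: tuple[str, str] | None = None  # flanking gene symbols for IGS
    genome_id: str | None = None

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def label(self) -> str:
        return f"({self.motif}){self.n_repeats}"

    @property
    def composition(self) -> tuple[str, ...]:
        return (self.canonical,)


@dataclass
class CompoundSSR:
    """Two or more SSRs separated by at most ``max_gap`` intervening bases."""

    components: list[SSRLocus]
    genome_id: str | None = None
    location_class: str | None = None
    context: tuple[str, str] | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.components[0].start, self.components[-1].end)

    start = property(lambda self: self.span[0])
    end = property(lambda self: self.span[1])
    length = property(lambda self: self.span[1] - self.span[0])

    @property
    def label(self) -> str:
        parts = [self.components[0].label]
        for prev, cur in zip(self.components, self.components[1:]):
            gap = cur.start - prev.end
            parts.append(";" if gap == 0 else f"{gap}n")
            parts.append(cur.label)
        return "".join(parts)

    @property
    def composition(self) -> tuple[str, ...]:
        return tuple(c.canonical for c in self.components)


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
    genome_id: str | None = None,
) -> list[SSRLocus]:
    """All perfect SSRs of unit length 1-6 meeting the repeat thresholds.

    A run is reported at the smallest primitive unit length that meets its
    threshold; re-reports of the same run at larger unit lengths are
    suppressed. Only complete repeats count towards the span.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = seq.upper()
    n = len(seq)
    accepted: list[SSRLocus] = []
    kept_spans: list[tuple[int, int]] = []
    for u in sorted(thresholds):
        min_rep = thresholds[u]
        i = 0
        while i + u <= n:
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            n_rep = (j - i) // u
            if n_rep >= min_rep:
                motif = seq[i : i + u]
                if is_primitive(motif):
                    s, e = i, i + u * n_rep
                    if not any(ks <= s and e <= ke for ks, ke in kept_spans):
                        accepted.append(
                            SSRLocus(
                                motif=motif,
                                n_repeats=n_rep,
                                span=(s, e),
                                genome_id=genome_id,
                            )
                        )
                        kept_spans.append((s, e))
            i = max(i + 1, j - u + 1)
    accepted.sort(key=lambda l: l.span)
    return accepted


def merge_compound(
    loci: list[SSRLocus],
    max_gap: int = DEFAULT_COMPOUND_GAP,
) -> list[SSRLocus | CompoundSSR]:
    """Fuse adjacent SSRs separated by at most ``max_gap`` bases.

    Input must be sorted by start. Runs of one stay plain ``SSRLocus``.
    """
    out: list[SSRLocus | CompoundSSR] = []
    group: list[SSRLocus] = []
    for locus in loci:
        if group and locus.start - group[-1].end <= max_gap:
            group.append(locus)
        else:
            if group:
                out.append(_finish_group(group))
            group = [locus]
    if group:
        out.append(_finish_group(group))
    return out


def _finish_group(group: list[SSRLocus]) -> SSRLocus | CompoundSSR:
    if len(group) == 1:
        return group[0]
    return CompoundSSR(components=list(group), genome_id=group[0].genome_id)


def locate_ssr(
    locus: SSRLocus | CompoundSSR,
    record: PlastomeRecord,
) -> SSRLocus | CompoundSSR:
    """Label a locus with its genomic context.

    CDS when the span intersects a protein-coding exon part, Intron when it
    lies inside the inter-part gap of a multi-part gene, otherwise IGS with
    the flanking gene symbols. Returns a copy with the fields filled in.
    """
    s, e = locus.span
    genic = record.features_of_kind("CDS", "tRNA", "rRNA")
    if not genic:
        return _with_location(locus, "IGS", ("", ""))
    for f in genic:
        if f.kind == "CDS":
            for ps, pe in f.parts:
                if s < pe and ps < e:
                    return _with_location(locus, "CDS", (f.name, f.name))
    for f in genic:
        parts = sorted(f.parts)
        for (a0, a1), (b0, b1) in zip(parts, parts[1:]):
            if b0 - a1 <= _INTRON_GAP_LIMIT and a1 <= s and e <= b0:
                return _with_location(locus, "Intron", (f.name, f.name))
    # non-CDS exon overlap still counts as intergenic context here
    left, right = "", ""
    best_l, best_r = None, None
    n = record.length
    for f in genic:
        dl = (s - f.end) % n
        dr = (f.start - e) % n
        if best_l is None or dl < best_l:
            best_l, left = dl, f.name
        if best_r is None or dr < best_r:
            best_r, right = dr, f.name
    return _with_location(locus, "IGS", (left, right))


def _with_location(locus, cls, ctx):
    if isinstance(locus, SSRLocus):
        return replace(locus, location_class=cls, context=ctx)
    return CompoundSSR(
        components=locus.components,
        genome_id=locus.genome_id,
        location_class=cls,
        context=ctx,
    )


# ---------------------------------------------------------------------------
# Cross-genome polymorphism
# ---------------------------------------------------------------------------

@dataclass
class SSRGroup:
    """A flank-anchored homologous SSR locus across genomes."""

    homology_key: str
    loci: dict[str, SSRLocus | CompoundSSR]  # genome id -> locus
    variable: bool
    location_class: str | None = None

    @property
    def genomes(self) -> list[str]:
        return list(self.loci)

    def spans(self) -> dict[str, tuple[int, int]]:
        return {g: l.span for g, l in self.loci.items()}


@dataclass
class PolymorphismResult:
    polymorphic: list[SSRGroup]
    monomorphic: list[SSRGroup]  # present in all genomes, no variation
    partial: list[SSRGroup]  # missing from at least one genome

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for grp in self.polymorphic:
            row = {
                "microsatellite": "/".join(
                    sorted({l.label for l in grp.loci.values()})
                ),
                "location": grp.location_class,
            }
            for g, l in grp.loci.items():
                row[f"{g}_start"] = l.start
                row[f"{g}_end"] = l.end
            rows.append(row)
        return pd.DataFrame(rows)


def _flanks(record: PlastomeRecord, span: tuple[int, int], flank_len: int):
    seq, n = record.sequence, record.length
    s, e = span
    if record.circular:
        left = "".join(seq[(s - flank_len + i) % n] for i in range(flank_len))
        right = "".join(seq[(e + i) % n] for i in range(flank_len))
    else:
        left = seq[max(0, s - flank_len) : s]
        right = seq[e : e + flank_len]
    return left, right


def _identity(a: str, b: str) -> float:
    if not a or not b or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def classify_polymorphic(
    per_genome_loci: dict[str, list[SSRLocus | CompoundSSR]],
    records: dict[str, PlastomeRecord],
    flank_len: int = 20,
    min_identity: float = 0.8,
) -> PolymorphismResult:
    """Group loci across genomes by flank anchors and call polymorphism.

    Each locus of the first genome is anchored on ``flank_len`` bases either
    side; in every other genome the best locus whose two flanks both reach
    ``min_identity`` ungapped identity joins the group. Groups found in all
    genomes are polymorphic when any two members differ in span length or
    motif composition.
    """
    genomes = list(per_genome_loci)
    if len(genomes) < 2:
        raise ValueError("polymorphism needs at least two genomes")
    ref = genomes[0]
    flank_cache: dict[str, list[tuple]] = {}
    for g in genomes:
        flank_cache[g] = [
            (locus, *_flanks(records[g], locus.span, flank_len))
            for locus in per_genome_loci[g]
        ]

    used: dict[str, set[int]] = {g: set() for g in genomes}
    complete: list[SSRGroup] = []
    partial: list[SSRGroup] = []
    for ref_locus, ref_l, ref_r in flank_cache[ref]:
        group = {ref: ref_locus}
        for g in genomes[1:]:
            best = None
            for idx, (locus, fl, fr) in enumerate(flank_cache[g]):
                if idx in used[g]:
                    continue
                il, ir = _identity(ref_l, fl), _identity(ref_r, fr)
                if il >= min_identity and ir >= min_identity:
                    score = (
                        -(il + ir),
                        abs(locus.start - ref_locus.start),
                        locus.start,
                        idx,
                    )
                    if best is None or score < best[0]:
                        best = (score, idx, locus)
            if best is not None:
                used[g].add(best[1])
                group[g] = best[2]
        lengths = {l.length for l in group.values()}
        comps = {l.composition for l in group.values()}
        grp = SSRGroup(
            homology_key=f"{ref_l}|{ref_r}",
            loci=group,
            variable=len(lengths) > 1 or len(comps) > 1,
            location_class=getattr(ref_locus, "location_class", None),
        )
        if len(group) == len(genomes):
            complete.append(grp)
        else:
            partial.append(grp)
    return PolymorphismResult(
        polymorphic=[g for g in complete if g.variable],
        monomorphic=[g for g in complete if not g.variable],
        partial=partial,
    )


def motif_summary(per_genome_loci: dict[str, list[SSRLocus]]) -> pd.DataFrame:
    """Counts of canonical motif classes per genome (simple loci only)."""
    rows = []
    for g, loci in per_genome_loci.items():
        for locus in loci:
            items = (
                locus.components if isinstance(locus, CompoundSSR) else [locus]
            )
            for it in items:
                rows.append(
                    {"genome": g, "canonical": it.canonical, "unit_len": it.unit_len}
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["genome", "unit_len", "canonical"])
        .size()
        .rename("count")
        .reset_index()
    )
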