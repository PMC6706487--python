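"""Seeded generator of annotated, circular, quadripartite plastome-like
genomes for a simulated genus, with a truth manifest for every downstream
stage.

An ancestral genome is assembled from explicit segments — spacers, gene
exons and introns, planted microsatellites — laid out as LSC + IRb + SSC,
with IRa appended as the exact reverse complement of IRb. Each species of
the genus is derived independently from the ancestor (a star phylogeny):
seeded point substitutions are applied per segment at region-specific
rates, and planted polymorphic SSRs are resized to their per-species repeat
counts. IRb and IRa stay identical within a species because IRa is rebuilt
from the mutated IRb, mimicking concerted evolution of the repeat.

Substitutions only, no indels: with per-site substitution probability theta
applied independently on each branch, the expected pairwise difference per
site is 2*theta - (4/3)*theta**2, keeping diversity expectations
closed-form.

Exactness guarantees recorded in the manifest:

* partition — guard bases at every junction stop the planted IR from
  extending, so IR detection recovers the planted intervals exactly;
* SSR truth — planted loci are flanked by non-extending guard bases, and
  background repeats (random or mutation-born) are broken by deterministic
  single-base edits, so the detector reports exactly the planted spans;
* gene truth — annotations are positional and immune to substitutions
  (start/stop codons and guard bases are excluded from mutation).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .plastome_io import GeneFeature, PlastomeRecord, reverse_complement
from .ssr import DEFAULT_THRESHOLDS, find_ssrs

__all__ = [
    "SimulationSpec",
    "PlantedSSR",
    "TruthManifest",
    "GenerationError",
    "default_planted_ssrs",
    "generate_genus",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


class GenerationError(ValueError):
    """A simulation spec that cannot be realised, naming the element."""


@dataclass
class PlantedSSR:
    """One microsatellite locus (simple or compound) to plant.

    ``components`` are ``(motif, per-species repeat counts)``; a compound
    locus has several components separated by the fixed ``gaps`` sequences.
    """

    components: list[tuple[str, tuple[int, ...]]]
    region: str  # 'LSC' | 'SSC' | 'IRB'
    placement: str = "IGS"  # 'IGS' | 'intron' | 'CDS'
    gaps: tuple[str, ...] = ()

    @property
    def polymorphic(self) -> bool:
        return any(len(set(counts)) > 1 for _, counts in self.components)

    def species_seq(self, sp: int) -> str:
        parts = []
        for i, (motif, counts) in enumerate(self.components):
            if i:
                parts.append(self.gaps[i - 1] if i - 1 < len(self.gaps) else "")
            parts.append(motif * counts[sp])
        return "".join(parts)


def default_planted_ssrs(n_species: int) -> list[PlantedSSR]:
    """Stock panel: 12 polymorphic and 6 monomorphic loci across LSC/SSC
    spacers, one intron and one coding exon. Counts cycle to ``n_species``
    and always meet the detection threshold, so every locus is present in
    every genome."""

    def c(*vals) -> tuple[int, ...]:
        return tuple(vals[i % len(vals)] for i in range(n_species))

    poly = [
        PlantedSSR([("T", c(10, 12, 11, 13, 10, 14))], "LSC"),
        PlantedSSR([("A", c(11, 10, 12, 10, 14, 11))], "LSC"),
        PlantedSSR([("AT", c(5, 6, 5, 7, 5, 6))], "LSC"),
        PlantedSSR([("TA", c(6, 5, 7, 5, 6, 5))], "SSC"),
        PlantedSSR([("AAG", c(4, 5, 4, 4, 6, 5))], "LSC"),
        PlantedSSR([("AAAT", c(3, 4, 3, 5, 3, 4))], "LSC"),
        PlantedSSR([("AATCT", c(3, 3, 4, 3, 5, 3))], "SSC"),
        PlantedSSR([("AATTCG", c(3, 4, 3, 3, 5, 4))], "LSC"),
        PlantedSSR([("T", c(10, 11, 12, 10, 13, 11))], "LSC", placement="intron"),
        PlantedSSR([("C", c(10, 12, 10, 11, 10, 12))], "LSC"),
        PlantedSSR([("AC", c(5, 5, 6, 5, 7, 6))], "LSC"),
        PlantedSSR(
            [("AAAT", c(3, 3, 4, 3, 5, 4)), ("CTT", c(4, 4, 4, 5, 6, 4))],
            "SSC",
            gaps=("GCAGTA",),
        ),
    ]
    mono = [
        PlantedSSR([("T", c(10))], "SSC"),
        PlantedSSR([("AT", c(5))], "LSC"),
        PlantedSSR([("TTC", c(4))], "LSC", placement="CDS"),
        PlantedSSR([("AAAT", c(3))], "SSC"),
        PlantedSSR([("T", c(10)), ("AG", c(5))], "LSC", gaps=("GCCA",)),
        PlantedSSR([("AATCT", c(3))], "LSC"),
    ]
    return poly + mono


@dataclass
class SimulationSpec:
    """Study conditions for one simulated genus."""

    seed: int = 0
    n_species: int = 5
    genome_length: int = 150_000
    ir_length: int = 24_500
    ssc_length: int = 17_500
    # gene plan (counts per region)
    lsc_cds: int = 18
    lsc_trna: int = 8
    ssc_cds: int = 8
    ssc_trna: int = 1
    ir_cds: int = 2
    ir_trna: int = 3
    ir_rrna: int = 4
    cds_len: int = 900
    trna_len: int = 75
    rrna_len: int = 1500
    intron_len: int = 700
    # substitution probabilities per site per branch
    background_rate: float = 0.002
    hotspot_rate: float = 0.02
    coding_rate: float = 0.0005
    n_hotspots: int = 5
    planted_ssrs: list[PlantedSSR] | None = None
    # junction scenarios
    junction_gene: bool = False  # plant a CDS crossing JLB into IRb
    junction_overlap: int = 101  # bases of that CDS inside IRb
    junction_gap: int | None = None  # exact gap between last LSC gene and JLB

    @property
    def lsc_length(self) -> int:
        return self.genome_length - 2 * self.ir_length - self.ssc_length

    def ssr_panel(self) -> list[PlantedSSR]:
        if self.planted_ssrs is not None:
            return self.planted_ssrs
        return default_planted_ssrs(self.n_species)

    def validate(self) -> None:
        if self.lsc_length <= 0:
            raise GenerationError("genome_length leaves no room for the LSC")
        if self.lsc_length < self.ssc_length:
            raise GenerationError("LSC would be shorter than SSC")
        if self.n_species < 2:
            raise GenerationError("n_species must be at least 2")
        for idx, plan in enumerate(self.ssr_panel()):
            for motif, counts in plan.components:
                if len(counts) != self.n_species:
                    raise GenerationError(
                        f"planted SSR #{idx} ({motif}): needs {self.n_species}"
                        f" per-species counts, got {len(counts)}"
                    )
                need = DEFAULT_THRESHOLDS[len(motif)]
                if min(counts) < need:
                    raise GenerationError(
                        f"planted SSR #{idx} ({motif}): repeat count "
                        f"{min(counts)} below detection threshold {need}"
                    )


# ---------------------------------------------------------------------------
# Segments and primitive builders
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    kind: str  # 'spacer' | 'exon' | 'intron' | 'ssr'
    region: str  # 'LSC' | 'IRB' | 'SSC'
    seq: str = ""
    rate: float = 0.0
    gene: tuple | None = None  # (name, kind, strand, part_index)
    ssr_index: int | None = None
    guard_first: str | None = None
    guard_last: str | None = None
    protect_edges: int = 0  # bases at each end excluded from mutation


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _pick_base(chars, pos: int, period: int) -> str:
    """A replacement base that breaks the repeat period at ``pos`` without
    matching the immediate neighbours (no new runs)."""
    forbidden = {chars[pos]}
    for q in (period, 1):
        if pos - q >= 0:
            forbidden.add(chars[pos - q])
        if pos + q < len(chars):
            forbidden.add(chars[pos + q])
    options = [b for b in _BASES if b not in forbidden]
    if not options:  # four distinct neighbours: any change breaks the period
        options = [b for b in _BASES if b != chars[pos]]
    return options[0]


_REDUCED_THRESHOLDS = {1: 8, 2: 4, 3: 3, 4: 2, 5: 2, 6: 2}


def _sanitize_segment(seq: str, protect: int = 0) -> str:
    """Break background repeats inside one ancestral segment.

    Reduced thresholds leave a safety margin so substitutions or segment
    joins cannot easily assemble a reportable repeat later. The first/last
    ``protect`` bases are never edited (start/stop codons, guards).
    """
    chars = list(seq)
    lo, hi = protect, len(chars) - protect
    for _ in range(50):
        hits = find_ssrs("".join(chars), _REDUCED_THRESHOLDS)
        hits = [h for h in hits if h.end > lo and h.start < hi]
        if not hits:
            break
        for h in hits:
            pos = min(max((h.start + h.end) // 2, lo), hi - 1)
            chars[pos] = _pick_base(chars, pos, h.unit_len)
    return "".join(chars)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _safe_codon(edge: str, avoid: str) -> str:
    """A glycine/serine-family codon whose relevant edge base differs from
    ``avoid`` (used to buttress a planted in-frame SSR)."""
    pool = ["GGA", "GGT", "GGC", "AGC", "TCA", "CCA"]
    for codon in pool:
        base = codon[-1] if edge == "last" else codon[0]
        if base != avoid:
            return codon
    raise AssertionError("unreachable")  # pragma: no cover


def _guard_char(avoid: str) -> str:
    for b in "GCAT":
        if b != avoid:
            return b
    return "G"  # pragma: no cover


# ---------------------------------------------------------------------------
# Layout of the ancestral genome
# ---------------------------------------------------------------------------

class _Layout:
    """Builds the ancestral segment list and remembers planted truths."""

    def __init__(self, spec: SimulationSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.segments: list[_Segment] = []
        self.gene_catalog: list[tuple[str, str, str]] = []  # name, kind, region
        self.intron_truth: dict[str, int] = {}
        self.alt_start_gene: str | None = None
        self.junction_gene_name: str | None = None
        self.hotspot_names: list[str] = []

    # -- gene builders ----------------------------------------------------

    def _cds_segments(
        self,
        name: str,
        region: str,
        strand: str,
        n_introns: int = 0,
        ssr_index: int | None = None,
        ssr_in_intron: int | None = None,
        alt_start: bool = False,
    ) -> list[_Segment]:
        spec, rng = self.spec, self.rng
        n_codons = max(10, spec.cds_len // 3)
        start = "ACG" if alt_start else "ATG"
        cds = start + _random_codons(rng, n_codons - 2) + "TAA"
        segs: list[_Segment] = []
        if ssr_index is not None:
            # in-frame SSR inside a single exon; boundary codons chosen so
            # the planted run cannot extend into the coding sequence
            plan = spec.ssr_panel()[ssr_index]
            motif = plan.components[0][0]
            cut = 3 * (len(cds) // 6)
            left = cds[: cut - 3] + _safe_codon("last", motif[-1])
            right = _safe_codon("first", motif[0]) + cds[cut + 3 :]
            segs.append(
                _Segment(
                    "exon", region, _sanitize_segment(left, 3), spec.coding_rate,
                    gene=(name, "CDS", strand, 0), protect_edges=3,
                )
            )
            segs.append(
                _Segment("ssr", region, "", 0.0, gene=(name, "CDS", strand, 0),
                         ssr_index=ssr_index)
            )
            segs.append(
                _Segment(
                    "exon", region, _sanitize_segment(right, 3), spec.coding_rate,
                    gene=(name, "CDS", strand, 0), protect_edges=3,
                )
            )
            return segs
        if strand == "-":
            cds = reverse_complement(cds)
        if n_introns == 0:
            return [
                _Segment("exon", region, _sanitize_segment(cds, 3),
                         spec.coding_rate, gene=(name, "CDS", strand, 0),
                         protect_edges=3)
            ]
        bounds = np.linspace(0, len(cds), n_introns + 2).astype(int)
        for k in range(n_introns + 1):
            exon = cds[bounds[k] : bounds[k + 1]]
            segs.append(
                _Segment("exon", region, _sanitize_segment(exon, 3),
                         spec.coding_rate, gene=(name, "CDS", strand, k),
                         protect_edges=3)
            )
            if k < n_introns:
                segs.extend(self._intron_segments(
                    region, ssr_in_intron if k == 0 else None
                ))
        self.intron_truth[name] = n_introns
        return segs

    def _intron_segments(self, region: str, ssr_index: int | None):
        spec, rng = self.spec, self.rng
        if ssr_index is None:
            return [
                _Segment("intron", region,
                         _sanitize_segment(_rand_seq(rng, spec.intron_len)),
                         spec.background_rate)
            ]
        motif_first = spec.ssr_panel()[ssr_index].components[0][0][0]
        motif_last = spec.ssr_panel()[ssr_index].components[-1][0][-1]
        half = spec.intron_len // 2
        return [
            _Segment("intron", region,
                     _sanitize_segment(_rand_seq(rng, half), 1),
                     spec.background_rate, guard_last=_guard_char(motif_last)),
            _Segment("ssr", region, "", 0.0, ssr_index=ssr_index),
            _Segment("intron", region,
                     _sanitize_segment(_rand_seq(rng, half), 1),
                     spec.background_rate, guard_first=_guard_char(motif_first)),
        ]

    def _rna_segments(self, name, kind, region, length, n_introns=0):
        spec, rng = self.spec, self.rng
        segs = []
        for k in range(n_introns + 1):
            segs.append(
                _Segment("exon", region,
                         _sanitize_segment(_rand_seq(rng, length)),
                         spec.coding_rate, gene=(name, kind, "+", k))
            )
            if k < n_introns:
                segs.extend(self._intron_segments(region, None))
        if n_introns:
            self.intron_truth[name] = n_introns
        return segs

    # -- whole-genome layout ----------------------------------------------

    def build(self) -> None:
        spec, rng = self.spec, self.rng
        panel = spec.ssr_panel()
        by_region: dict[str, list[int]] = {"LSC": [], "SSC": [], "IRB": []}
        intron_ssr = None
        cds_ssr = None
        for i, plan in enumerate(panel):
            if plan.placement == "intron":
                intron_ssr = i
            elif plan.placement == "CDS":
                cds_ssr = i
            else:
                by_region[plan.region].append(i)

        lsc_items: list[list[_Segment]] = []
        gnum = 0
        for j in range(spec.lsc_cds):
            gnum += 1
            name = f"g{gnum:02d}"
            n_introns = {1: 1, 2: 2, 4: 1}.get(j, 0)
            kwargs = {}
            if j == 3 and intron_ssr is not None:
                n_introns = 1
                kwargs["ssr_in_intron"] = intron_ssr
            if j == 5 and cds_ssr is not None:
                n_introns = 0
                kwargs["ssr_index"] = cds_ssr
            alt = j == 6
            strand = "+" if (n_introns or kwargs) else ("+" if j % 2 else "-")
            segs = self._cds_segments(
                name, "LSC", strand, n_introns, alt_start=alt, **kwargs
            )
            if alt:
                self.alt_start_gene = name
            lsc_items.append(segs)
            self.gene_catalog.append((name, "CDS", "LSC"))
        for j in range(spec.lsc_trna):
            name = f"t{j + 1:02d}"
            lsc_items.append(
                self._rna_segments(name, "tRNA", "LSC", spec.trna_len,
                                   1 if j == 1 else 0)
            )
            self.gene_catalog.append((name, "tRNA", "LSC"))

        ir_items: list[list[_Segment]] = []
        for j in range(spec.ir_rrna):
            name = f"r{j + 1:02d}"
            ir_items.append(self._rna_segments(name, "rRNA", "IRB", spec.rrna_len))
            self.gene_catalog.append((name, "rRNA", "IRB"))
        for j in range(spec.ir_trna):
            name = f"t{spec.lsc_trna + j + 1:02d}"
            ir_items.append(self._rna_segments(name, "tRNA", "IRB", spec.trna_len))
            self.gene_catalog.append((name, "tRNA", "IRB"))
        for j in range(spec.ir_cds):
            gnum += 1
            name = f"g{gnum:02d}"
            ir_items.append(self._cds_segments(name, "IRB", "+"))
            self.gene_catalog.append((name, "CDS", "IRB"))

        ssc_items: list[list[_Segment]] = []
        for j in range(spec.ssc_cds):
            gnum += 1
            name = f"g{gnum:02d}"
            n_introns = 1 if j == 1 else 0
            strand = "+" if n_introns else ("-" if j % 2 else "+")
            ssc_items.append(self._cds_segments(name, "SSC", strand, n_introns))
            self.gene_catalog.append((name, "CDS", "SSC"))
        for j in range(spec.ssc_trna):
            name = f"t{spec.lsc_trna + spec.ir_trna + j + 1:02d}"
            ssc_items.append(
                self._rna_segments(name, "tRNA", "SSC", spec.trna_len)
            )
            self.gene_catalog.append((name, "tRNA", "SSC"))

        junction_lsc: list[_Segment] | None = None
        junction_irb: list[_Segment] | None = None
        if spec.junction_gene:
            gnum += 1
            name = f"g{gnum:02d}"
            self.junction_gene_name = name
            total = 3 * ((250 + spec.junction_overlap) // 3 + 2)
            l1 = total - spec.junction_overlap
            cds = "ATG" + _random_codons(rng, total // 3 - 2) + "TAA"
            # the base just left of JLB must not pair with the genome's
            # first base (guard 'A'), or the planted IR would extend
            while cds[l1 - 1] == _COMP["A"]:
                cds = "ATG" + _random_codons(rng, total // 3 - 2) + "TAA"
            left = _sanitize_segment(cds[:l1], 3)
            if left[-1] == _COMP["A"]:  # sanitizer touched the edge base
                left = left[:-1] + cds[l1 - 1]
            junction_lsc = [
                _Segment("exon", "LSC", left, spec.coding_rate,
                         gene=(name, "CDS", "+", 0), protect_edges=3)
            ]
            junction_irb = [
                _Segment("exon", "IRB", _sanitize_segment(cds[l1:], 3),
                         spec.coding_rate, gene=(name, "CDS", "+", 0),
                         protect_edges=3)
            ]
            self.gene_catalog.append((name, "CDS", "LSC"))

        self._assemble_region(
            "LSC", spec.lsc_length, lsc_items, by_region["LSC"],
            hotspots=spec.n_hotspots, tail_segs=junction_lsc,
            tail_gap=spec.junction_gap,
        )
        self._assemble_region(
            "IRB", spec.ir_length, ir_items, by_region["IRB"],
            head_segs=junction_irb,
        )
        self._assemble_region("SSC", spec.ssc_length, ssc_items, by_region["SSC"])

    def _assemble_region(
        self,
        region: str,
        target_len: int,
        items: list[list[_Segment]],
        ssr_indices: list[int],
        hotspots: int = 0,
        head_segs: list[_Segment] | None = None,
        tail_segs: list[_Segment] | None = None,
        tail_gap: int | None = None,
    ) -> None:
        """Interleave content items with spacers so the region length equals
        ``target_len`` in the species with the longest SSR alleles.

        The first and last base of each region are fixed guard 'A's (unless
        a junction gene occupies the edge), which prevents the planted IR
        from extending across any junction.
        """
        spec, rng = self.spec, self.rng
        panel = spec.ssr_panel()
        head_len = sum(len(s.seq) for s in head_segs or [])
        tail_len = sum(len(s.seq) for s in tail_segs or [])
        def _max_allele(i: int) -> int:
            return max(
                len(panel[i].species_seq(sp)) for sp in range(spec.n_species)
            )

        content_len = sum(
            len(s.seq) if s.kind != "ssr" else _max_allele(s.ssr_index)
            for item in items
            for s in item
        )
        ssr_len = sum(_max_allele(i) for i in ssr_indices)
        n_spacers = len(items) + 1
        fixed_last = tail_gap is not None
        n_free_spacers = n_spacers - 1 if fixed_last else n_spacers
        free = (
            target_len - content_len - ssr_len - head_len - tail_len
            - (tail_gap or 0)
        )
        if free < 40 * n_free_spacers:
            raise GenerationError(
                f"region {region}: content leaves insufficient spacer room "
                f"({free} bp over {n_free_spacers} spacers in {target_len} bp)"
            )
        base = free // n_free_spacers
        spacer_lens = [base] * n_free_spacers
        spacer_lens[-1] += free - base * n_free_spacers
        if fixed_last:
            spacer_lens.append(tail_gap)

        interior = list(range(1, n_spacers - 1))
        if len(ssr_indices) + hotspots > len(interior):
            raise GenerationError(
                f"region {region}: not enough spacers for "
                f"{len(ssr_indices)} SSRs + {hotspots} hotspots"
            )
        perm = rng.permutation(len(interior))
        shuffled = [interior[i] for i in perm]
        ssr_at = {shuffled[i]: idx for i, idx in enumerate(ssr_indices)}
        hot_at = set(shuffled[len(ssr_indices) : len(ssr_indices) + hotspots])

        if head_segs:
            self.segments.extend(head_segs)
        for si in range(n_spacers):
            ln = spacer_lens[si]
            rate = spec.hotspot_rate if si in hot_at else spec.background_rate
            seq = _sanitize_segment(_rand_seq(rng, max(ln, 0)), 1)
            is_first = si == 0 and not head_segs
            is_last = si == n_spacers - 1 and not tail_segs
            if si in ssr_at:
                idx = ssr_at[si]
                motif_first = panel[idx].components[0][0][0]
                motif_last = panel[idx].components[-1][0][-1]
                half = ln // 2
                left = _Segment("spacer", region, seq[:half], rate,
                                guard_last=_guard_char(motif_last),
                                guard_first="A" if is_first else None)
                right = _Segment("spacer", region, seq[half:], rate,
                                 guard_first=_guard_char(motif_first),
                                 guard_last="A" if is_last else None)
                self.segments.append(left)
                self.segments.append(
                    _Segment("ssr", region, "", 0.0, ssr_index=idx)
                )
                self.segments.append(right)
            else:
                self.segments.append(
                    _Segment("spacer", region, seq, rate,
                             guard_first="A" if is_first else None,
                             guard_last="A" if is_last else None)
                )
            if si in hot_at:
                left_g = _item_gene_name(items[si - 1], "last")
                right_g = _item_gene_name(items[si], "first")
                self.hotspot_names.append(f"{left_g}-{right_g}")
            if si < len(items):
                self.segments.extend(items[si])
        if tail_segs:
            self.segments.extend(tail_segs)


def _item_gene_name(item: list[_Segment], edge: str) -> str:
    genes = [s.gene[0] for s in item if s.gene]
    if not genes:
        return "?"
    return genes[-1] if edge == "last" else genes[0]


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    species: list[str]
    partitions: dict[str, dict]
    gene_truth: dict
    ssr_truth: list[dict]
    hotspot_truth: list[dict]
    rates: dict
    mutation_counts: dict[str, int]
    repairs: dict[str, int]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def polymorphic_ids(self) -> list[int]:
        return [t["id"] for t in self.ssr_truth if t["polymorphic"]]


# ---------------------------------------------------------------------------
# Species generation
# ---------------------------------------------------------------------------

def generate_genus(spec: SimulationSpec) -> tuple[list[PlastomeRecord], TruthManifest]:
    """Generate the genus: one annotated record per species plus the truth
    manifest. The same spec (same seed) reproduces byte-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    layout = _Layout(spec, rng)
    layout.build()

    records: list[PlastomeRecord] = []
    partitions: dict[str, dict] = {}
    ssr_spans: dict[str, list] = {}
    mutation_counts: dict[str, int] = {}
    repair_counts: dict[str, int] = {}
    species_names = [f"sim{i + 1:02d}" for i in range(spec.n_species)]

    for sp, sp_name in enumerate(species_names):
        sp_rng = np.random.default_rng([spec.seed, 7919 + sp])
        genome, feats, part, spans, nmut, nrep = _build_species(
            spec, layout, sp, sp_rng
        )
        records.append(
            PlastomeRecord(
                id=sp_name,
                sequence=genome,
                circular=True,
                features=feats,
                description=f"synthetic plastome {sp_name}",
            )
        )
        partitions[sp_name] = part
        ssr_spans[sp_name] = spans
        mutation_counts[sp_name] = nmut
        repair_counts[sp_name] = nrep

    panel = spec.ssr_panel()
    ssr_truth = []
    for i, plan in enumerate(panel):
        ssr_truth.append(
            {
                "id": i,
                "region": plan.region,
                "placement": plan.placement,
                "polymorphic": plan.polymorphic,
                "components": [
                    [motif, list(counts)] for motif, counts in plan.components
                ],
                "gaps": list(plan.gaps),
                "component_spans": {
                    s: [list(x) for x in ssr_spans[s][i][0]]
                    for s in species_names
                },
                "full_span": {s: list(ssr_spans[s][i][1]) for s in species_names},
            }
        )

    n_pcg = sum(1 for _, k, _ in layout.gene_catalog if k == "CDS")
    n_trna = sum(1 for _, k, _ in layout.gene_catalog if k == "tRNA")
    n_rrna = sum(1 for _, k, _ in layout.gene_catalog if k == "rRNA")
    gene_truth = {
        "n_pcg": n_pcg,
        "n_trna": n_trna,
        "n_rrna": n_rrna,
        "n_unique": n_pcg + n_trna + n_rrna,
        "duplicated_in_ir": sorted(
            n for n, _, r in layout.gene_catalog if r == "IRB"
        ),
        "intron_bearing": dict(sorted(layout.intron_truth.items())),
        "alternative_starts": (
            {layout.alt_start_gene: "ACG"} if layout.alt_start_gene else {}
        ),
        "junction_gene": layout.junction_gene_name,
        "junction_overlap": (
            spec.junction_overlap if layout.junction_gene_name else None
        ),
        "junction_gap": spec.junction_gap,
    }
    manifest = TruthManifest(
        species=species_names,
        partitions=partitions,
        gene_truth=gene_truth,
        ssr_truth=ssr_truth,
        hotspot_truth=[
            {"name": n, "rate": spec.hotspot_rate} for n in layout.hotspot_names
        ],
        rates={
            "background": spec.background_rate,
            "hotspot": spec.hotspot_rate,
            "coding": spec.coding_rate,
        },
        mutation_counts=mutation_counts,
        repairs=repair_counts,
    )
    return records, manifest


def _mutate(seg: _Segment, rng: np.random.Generator) -> tuple[str, int]:
    seq = seg.seq
    if seg.rate <= 0 or not seq:
        return seq, 0
    mask = rng.random(len(seq)) < seg.rate
    if seg.protect_edges:
        mask[: seg.protect_edges] = False
        mask[len(seq) - seg.protect_edges :] = False
    if seg.guard_first:
        mask[0] = False
    if seg.guard_last:
        mask[-1] = False
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return seq, 0
    chars = list(seq)
    shifts = rng.integers(1, 4, size=len(idx))
    for i, sh in zip(idx, shifts):
        chars[i] = _BASES[(_BASES.index(chars[i]) + int(sh)) % 4]
    return "".join(chars), len(idx)


def _build_species(spec, layout, sp, rng):
    chunks: list[str] = []
    pos = 0
    part_spans: dict[tuple, list[int]] = {}
    gene_meta: dict[str, tuple] = {}
    ssr_span_acc: dict[int, tuple] = {}
    protected: list[tuple[int, int]] = []
    region_bounds: dict[str, list[int]] = {}
    nmut = 0

    for seg in layout.segments:
        region_bounds.setdefault(seg.region, [pos, pos])
        if seg.kind == "ssr":
            plan = spec.ssr_panel()[seg.ssr_index]
            comp_spans = []
            p = pos
            for k, (motif, counts) in enumerate(plan.components):
                if k:
                    p += len(plan.gaps[k - 1]) if k - 1 < len(plan.gaps) else 0
                comp_spans.append((p, p + len(motif) * counts[sp]))
                p += len(motif) * counts[sp]
            seq = plan.species_seq(sp)
            ssr_span_acc[seg.ssr_index] = (comp_spans, (pos, pos + len(seq)))
            protected.append((pos, pos + len(seq)))
        else:
            seq, k = _mutate(seg, rng)
            nmut += k
            if seg.guard_first:
                seq = seg.guard_first + seq[1:]
                protected.append((pos, pos + 1))
            if seg.guard_last:
                seq = seq[:-1] + seg.guard_last
                protected.append((pos + len(seq) - 1, pos + len(seq)))
            if seg.protect_edges:
                e = seg.protect_edges
                protected.append((pos, pos + e))
                protected.append((pos + len(seq) - e, pos + len(seq)))
        if seg.gene is not None:
            key = (seg.gene[0], seg.gene[3])
            span = part_spans.setdefault(key, [pos, pos])
            span[1] = pos + len(seq)
            gene_meta[seg.gene[0]] = (seg.gene[1], seg.gene[2])
        chunks.append(seq)
        region_bounds[seg.region][1] = pos + len(seq)
        pos += len(seq)

    template = "".join(chunks)
    irb_start, irb_end = region_bounds["IRB"]
    ira_start = len(template)
    genome = template + reverse_complement(template[irb_start:irb_end])
    n = len(genome)

    features: list[GeneFeature] = []
    by_gene: dict[str, list[tuple[int, list[int]]]] = {}
    for (name, part_idx), span in part_spans.items():
        by_gene.setdefault(name, []).append((part_idx, span))
    for name, plist in by_gene.items():
        kind, strand = gene_meta[name]
        parts = [tuple(span) for _, span in sorted(plist)]
        features.append(
            GeneFeature(name=name, kind=kind, strand=strand, parts=list(parts))
        )
        if all(irb_start <= s and e <= irb_end for s, e in parts):
            mirrored = sorted(
                (ira_start + irb_end - e, ira_start + irb_end - s)
                for s, e in parts
            )
            features.append(
                GeneFeature(
                    name=name,
                    kind=kind,
                    strand="-" if strand == "+" else "+",
                    parts=mirrored,
                )
            )

    genome, nrep = _repair_spurious_ssrs(
        genome, ssr_span_acc, protected, irb_start, irb_end, ira_start
    )

    partition_truth = {
        "lsc": [0, region_bounds["LSC"][1]],
        "irb": [irb_start, irb_end],
        "ssc": [region_bounds["SSC"][0], region_bounds["SSC"][1]],
        "ira": [ira_start, n],
        "junctions": {
            "JLB": irb_start,
            "JSB": region_bounds["SSC"][0],
            "JSA": ira_start,
            "JLA": 0,
        },
        "length": n,
    }
    spans_list = [ssr_span_acc[i] for i in sorted(ssr_span_acc)]
    return genome, features, partition_truth, spans_list, nmut, nrep


def _repair_spurious_ssrs(
    genome: str,
    ssr_span_acc: dict[int, tuple],
    protected: list[tuple[int, int]],
    irb_start: int,
    irb_end: int,
    ira_start: int,
) -> tuple[str, int]:
    """Break background SSRs by deterministic single-base edits so that
    detection recovers exactly the planted loci. Edits inside either IR
    copy are mirrored into the other so the copies stay identical."""
    expected = set()
    for comp_spans, _ in ssr_span_acc.values():
        expected.update(tuple(s) for s in comp_spans)
    protected_iv = sorted(protected)

    def is_protected(p: int) -> bool:
        for s, e in protected_iv:
            if s <= p < e:
                return True
            if s > p:
                break
        return False

    def ira_partner(p: int) -> int | None:
        """Mirror position in the other IR copy, if p lies in an IR."""
        if irb_start <= p < irb_end:
            return ira_start + (irb_end - 1 - p)
        if ira_start <= p:
            return irb_end - 1 - (p - ira_start)
        return None

    chars = list(genome)
    repairs = 0
    for _ in range(80):
        hits = [h for h in find_ssrs("".join(chars)) if h.span not in expected]
        if not hits:
            return "".join(chars), repairs
        for h in hits:
            fixed = False
            for p in range(h.start + 1, h.end - 1):
                partner = ira_partner(p)
                if is_protected(p):
                    continue
                if partner is not None and is_protected(partner):
                    continue
                chars[p] = _pick_base(chars, p, h.unit_len)
                if partner is not None:
                    chars[partner] = _COMP[chars[p]]
                repairs += 1
                fixed = True
                break
            if not fixed:
                raise GenerationError(
                    f"cannot break spurious SSR at {h.span} ({h.motif})"
                )
    raise GenerationError("spurious SSR repair did not converge")
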