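"""Reading, writing and sequence extraction for annotated plastome records.

Plastomes are circular molecules; deposited flat files linearize them at an
arbitrary origin. Internally every coordinate is 0-based half-open on the
linearized sequence, and features that span the origin are represented with a
``wraps_origin`` flag. GenBank I/O converts to and from the flat file's
1-based inclusive convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "PlastomeRecord",
    "PlastomeParseError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "extract_feature_sequence",
    "gc_fraction",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: feature kinds carried through from flat files, in inventory priority order
FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "gene")


class PlastomeParseError(ValueError):
    """Raised when a flat file cannot be interpreted as a plastome record."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene-level feature.

    ``parts`` holds ordered ``[start, end)`` intervals on the linearized
    sequence; more than one part encodes introns (contiguous genes) or
    trans-splicing (rps12). ``strand`` applies to the whole feature; the
    biological sequence of a minus-strand feature is the reverse complement
    of the concatenated parts.
    """

    name: str
    kind: str  # one of FEATURE_KINDS
    strand: str  # '+' or '-'
    parts: list[tuple[int, int]]
    notes: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no location parts")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r} has bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def n_introns(self) -> int:
        """Intron count for a contiguous (non-trans-spliced) feature."""
        return len(self.parts) - 1

    def span_length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class PlastomeRecord:
    """An annotated (usually circular) plastid genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"feature {f.name!r} part [{s},{e}) outside [0,{n})"
                    )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in kinds]


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

def _feature_name(sf: SeqFeature) -> str | None:
    q = sf.qualifiers
    for key in ("gene", "product", "locus_tag"):
        if key in q and q[key]:
            return str(q[key][0])
    return None


def _convert_feature(sf: SeqFeature, record_id: str) -> GeneFeature:
    name = _feature_name(sf) or sf.type
    loc = sf.location
    if loc is None:
        raise PlastomeParseError(f"{record_id}: feature {name!r} has no location")
    parts = []
    for p in loc.parts:
        parts.append((int(p.start), int(p.end)))
    strand = "-" if loc.strand == -1 else "+"
    if strand == "-":
        # Biopython lists complement(join(...)) parts 5'->3' on the minus
        # strand; store them in genomic order instead.
        parts = sorted(parts)
    notes = ";".join(sf.qualifiers.get("note", []))
    return GeneFeature(name=name, kind=sf.type, strand=strand, parts=parts, notes=notes)


def read_genbank(path) -> list[PlastomeRecord]:
    """Read every record of a GenBank flat file into PlastomeRecords.

    Gene names come from the ``gene`` qualifier, falling back to ``product``.
    Joined locations and complement strands are supported; coordinates are
    converted to 0-based half-open.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq:
            raise PlastomeParseError(f"{rec.id}: empty sequence")
        feats = []
        for sf in rec.features:
            if sf.type not in FEATURE_KINDS:
                continue
            try:
                feats.append(_convert_feature(sf, rec.id))
            except PlastomeParseError:
                raise
            except Exception as exc:  # malformed location
                raise PlastomeParseError(
                    f"{rec.id}: malformed location for feature "
                    f"{_feature_name(sf)!r}: {exc}"
                ) from exc
        circular = rec.annotations.get("topology", "circular") == "circular"
        records.append(
            PlastomeRecord(
                id=rec.id.split(".")[0] if rec.id else rec.name,
                sequence=seq,
                circular=circular,
                features=feats,
                description=rec.description,
            )
        )
    if not records:
        raise PlastomeParseError(f"{path}: no GenBank records found")
    return records


def _to_seqrecord(record: PlastomeRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id,
        description=record.description or record.id,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    strand_map = {"+": 1, "-": -1}
    for f in record.features:
        locs = [SimpleLocation(s, e, strand_map[f.strand]) for s, e in f.parts]
        if f.strand == "-" and len(locs) > 1:
            locs = locs[::-1]  # back to 5'->3' part order for writing
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.notes:
            quals["note"] = [f.notes]
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    return rec


def write_genbank(records, path) -> None:
    """Write PlastomeRecords as a GenBank flat file (1-based inclusive)."""
    if isinstance(records, PlastomeRecord):
        records = [records]
    SeqIO.write([_to_seqrecord(r) for r in records], str(path), "genbank")


def read_fasta(path) -> list[PlastomeRecord]:
    """Read a FASTA file into unannotated PlastomeRecords."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise PlastomeParseError(f"{rec.id}: empty sequence")
        out.append(PlastomeRecord(id=rec.id, sequence=seq, description=rec.description))
    return out


def write_fasta(records, path) -> None:
    if isinstance(records, PlastomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_feature_sequence(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Spliced biological sequence of a feature (5'->3').

    Parts are concatenated in genomic order and the result is
    reverse-complemented for minus-strand features. A part given as
    ``(s, e)`` with ``s > e`` wraps across the origin of a circular record.
    """
    chunks = []
    n = record.length
    for s, e in feature.parts:
        if s <= e:
            chunks.append(record.sequence[s:e])
        else:
            if not record.circular:
                raise ValueError(
                    f"feature {feature.name!r} wraps origin of a linear record"
                )
            chunks.append(record.sequence[s:] + record.sequence[:e])
        if not record.circular and e > n:
            raise ValueError(f"feature {feature.name!r} exceeds linear sequence")
    seq = "".join(chunks)
    return reverse_complement(seq) if feature.strand == "-" else seq


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC fraction undefined: no unambiguous bases")
    return gc / denom
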