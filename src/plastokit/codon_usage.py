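"""Codon-usage statistics for plastid protein-coding genes.

Implements the three classic synonymous-codon-bias summaries:

* RSCU (relative synonymous codon usage) — observed codon count divided by
  the uniform within-family expectation; 1 means no bias for that codon.
* ENc (effective number of codons, Wright 1990) — ranges from 20, one codon
  per amino acid, to 61, equal use of all synonymous codons. Computed from
  the family "homozygosity" F of each degeneracy class.
* CBI (codon bias index, Bennetzen & Hall) — excess use of a preferred codon
  set over the uniform expectation; 0 = no bias, 1 = only preferred codons.

All three use the bacterial/plastid genetic code (translation table 11):
nine 2-fold, one 3-fold (Ile), five 4-fold and three 6-fold (Leu, Ser, Arg)
degenerate families; Met and Trp are single-codon and excluded, stop codons
are excluded from family statistics but included in codon totals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonUsageTable",
    "CodonBiasSummary",
    "PLASTID_CODON_TO_AA",
    "SYNONYMOUS_FAMILIES",
    "count_codons",
    "rscu",
    "enc",
    "cbi",
    "preferred_codons",
    "aa_frequencies",
    "codon_table_frame",
    "bias_summary",
]

_table = CodonTable.unambiguous_dna_by_id[11]

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]

#: codon -> one-letter amino acid, '*' for stops (plastid code, table 11)
PLASTID_CODON_TO_AA: dict[str, str] = {
    c: (_table.forward_table[c] if c in _table.forward_table else "*")
    for c in ALL_CODONS
}

#: amino acid -> synonymous codon family (sense codons only)
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _c, _aa in PLASTID_CODON_TO_AA.items():
    if _aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_c)
for _fam in SYNONYMOUS_FAMILIES.values():
    _fam.sort()

STOP_CODONS = tuple(c for c, aa in PLASTID_CODON_TO_AA.items() if aa == "*")

#: Wright's degeneracy-class structure under code 11:
#: nine 2-fold, one 3-fold, five 4-fold, three 6-fold families
DEGENERACY_CLASSES: dict[int, list[str]] = {}
for _aa, _fam in SYNONYMOUS_FAMILIES.items():
    DEGENERACY_CLASSES.setdefault(len(_fam), []).append(_aa)
for _v in DEGENERACY_CLASSES.values():
    _v.sort()


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int
    total_cds_bases: int
    n_sequences: int
    warnings: list[str] = field(default_factory=list)

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in SYNONYMOUS_FAMILIES[aa]}


@dataclass
class CodonBiasSummary:
    enc: float
    cbi: float
    f_bar: dict[int, float]
    preferred_set: dict[str, str]


def count_codons(cds_seqs: list[str]) -> CodonUsageTable:
    """Count codons in frame 0 over a set of spliced CDS sequences.

    Stop codons are included in the totals. Sequences whose length is not a
    multiple of 3 contribute their complete codons; the remainder is dropped
    with a warning. An internal stop is recorded as a warning only.
    """
    counts = {c: 0 for c in ALL_CODONS}
    notes: list[str] = []
    total = 0
    bases = 0
    for idx, seq in enumerate(cds_seqs):
        seq = seq.upper()
        if len(seq) % 3 != 0:
            notes.append(f"sequence {idx}: length {len(seq)} not divisible by 3")
        ncod = len(seq) // 3
        for i in range(ncod):
            codon = seq[3 * i : 3 * i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
                bases += 3
                if codon in STOP_CODONS and i < ncod - 1:
                    notes.append(f"sequence {idx}: internal stop {codon} at codon {i}")
    return CodonUsageTable(
        counts=counts,
        total_codons=total,
        total_cds_bases=bases,
        n_sequences=len(cds_seqs),
        warnings=notes,
    )


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU(c) = family_size * X(c) / sum of X over the synonymous family.

    Codons of families with zero observations are absent from the result.
    """
    out: dict[str, float] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        tot = sum(table.counts.get(c, 0) for c in fam)
        if tot == 0:
            continue
        k = len(fam)
        for c in fam:
            out[c] = k * table.counts.get(c, 0) / tot
    return out


def _family_homozygosity(counts: dict[str, int]) -> tuple[float, int] | None:
    """Wright's F-hat for one family; None when n <= 1."""
    n = sum(counts.values())
    if n <= 1:
        return None
    s = sum((x / n) ** 2 for x in counts.values())
    f = (n * s - 1) / (n - 1)
    return f, n


def enc(table: CodonUsageTable) -> float:
    """Wright's effective number of codons.

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean family
    homozygosity of degeneracy class k. Families with at most one codon
    observed are excluded from their class mean. A missing 3-fold class is
    estimated from the average of 1/F2 and 1/F4 (Wright's rule); other
    empty classes make ENc undefined. The result is clamped to 61.
    """
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            res = _family_homozygosity(table.family_counts(aa))
            if res is not None and res[0] > 0:
                fs.append(res[0])
        if fs:
            class_means[k] = sum(fs) / len(fs)

    weights = {2: 9, 3: 1, 4: 5, 6: 3}
    if 2 not in class_means or 4 not in class_means or 6 not in class_means:
        raise ValueError("ENc undefined: a degeneracy class has no usable family")
    total = 2.0
    for k, w in weights.items():
        if k in class_means:
            total += w / class_means[k]
        elif k == 3:
            total += w * (1 / class_means[2] + 1 / class_means[4]) / 2
    return min(total, 61.0)


def preferred_codons(table: CodonUsageTable) -> dict[str, str]:
    """Highest-RSCU codon per multi-codon family (ties: alphabetic first)."""
    r = rscu(table)
    out: dict[str, str] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) < 2:
            continue
        scored = [c for c in fam if c in r]
        if not scored:
            continue
        best = max(r[c] for c in scored)
        out[aa] = sorted(c for c in scored if r[c] == best)[0]
    return out


def cbi(table: CodonUsageTable, preferred: dict[str, str] | None = None) -> float:
    """Codon bias index over multi-codon families.

    CBI = (Npref - Nran) / (Ntot - Nran) where Ntot counts codons in
    families with >= 2 synonymous codons, Npref those matching the preferred
    set, and Nran the uniform expectation sum(n_family / family_size). The
    default preferred set is derived from the same table (highest RSCU).
    """
    if preferred is None:
        preferred = preferred_codons(table)
    n_tot = 0
    n_pref = 0
    n_ran = 0.0
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) < 2:
            continue
        n_fam = sum(table.counts.get(c, 0) for c in fam)
        if n_fam == 0:
            continue
        if aa not in preferred:
            raise ValueError(f"preferred set missing amino acid {aa}")
        n_tot += n_fam
        n_pref += table.counts.get(preferred[aa], 0)
        n_ran += n_fam / len(fam)
    if n_tot == 0 or n_tot == n_ran:
        raise ValueError("CBI undefined: no usable multi-codon families")
    return (n_pref - n_ran) / (n_tot - n_ran)


def aa_frequencies(table: CodonUsageTable) -> dict[str, float]:
    """Percentage of sense codons per amino acid; stops under key '*'.

    The '*' entry is the stop fraction of all codons; amino-acid
    percentages are of sense codons, so they sum to 100.
    """
    if table.total_codons == 0:
        raise ValueError("empty codon table")
    sense = sum(
        v for c, v in table.counts.items() if PLASTID_CODON_TO_AA[c] != "*"
    )
    if sense == 0:
        raise ValueError("no sense codons")
    out: dict[str, float] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        out[aa] = 100.0 * sum(table.counts.get(c, 0) for c in fam) / sense
    out["*"] = 100.0 * (table.total_codons - sense) / table.total_codons
    return out


def bias_summary(
    table: CodonUsageTable, preferred: dict[str, str] | None = None
) -> CodonBiasSummary:
    """ENc, CBI, per-class mean homozygosity and the preferred set used."""
    pref = preferred if preferred is not None else preferred_codons(table)
    f_bar: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = [
            r[0]
            for aa in aas
            if (r := _family_homozygosity(table.family_counts(aa))) is not None
        ]
        if fs:
            f_bar[k] = sum(fs) / len(fs)
    return CodonBiasSummary(
        enc=enc(table), cbi=cbi(table, pref), f_bar=f_bar, preferred_set=pref
    )


def codon_table_frame(table: CodonUsageTable) -> pd.DataFrame:
    """One row per codon: codon, amino_acid, count, rscu."""
    r = rscu(table)
    rows = []
    for c in ALL_CODONS:
        rows.append(
            {
                "codon": c,
                "amino_acid": PLASTID_CODON_TO_AA[c],
                "count": table.counts.get(c, 0),
                "rscu": round(r[c], 4) if c in r else float("nan"),
            }
        )
    return pd.DataFrame(rows)
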