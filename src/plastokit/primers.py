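"""Primer proposal for divergence hotspots.

Candidate primers sit in conserved, gap-free windows of the hotspot
alignment so that one pair amplifies the variable core in every genome of
the group. Melting temperature uses the simple GC formula
``Tm = 64.9 + 41 * (gc - 16.4) / length`` (recorded in the output); no
Primer3-style hairpin/dimer/salt thermodynamics are attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .plastome_io import reverse_complement

__all__ = ["PrimerPair", "primer_tm", "propose_primers", "primer_frame"]

MIN_PRIMER_LEN = 18
MAX_PRIMER_LEN = 24
TM_FORMULA = "Tm = 64.9 + 41*(GC - 16.4)/N (simple GC formula)"


def primer_tm(seq: str) -> float:
    """Melting temperature by the simple GC-count formula (degrees C)."""
    if len(seq) < 14:
        raise ValueError(f"primer too short for Tm ({len(seq)} < 14)")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in primer {seq!r}")
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41 * (gc - 16.4) / len(seq)


@dataclass
class PrimerPair:
    forward: str
    reverse: str  # 5'->3' on the minus strand
    tm_f: float
    tm_r: float
    product_size: int  # in the first (reference) genome
    target_region: str
    product_sizes: dict[str, int] = field(default_factory=dict)
    forward_span: tuple[int, int] = (0, 0)  # alignment columns
    reverse_span: tuple[int, int] = (0, 0)


def _conserved_runs(rows: list[str]) -> list[tuple[int, int]]:
    """Maximal runs of columns identical in all rows, gap- and N-free."""
    length = len(rows[0])
    runs = []
    start = None
    for i in range(length):
        chars = {r[i] for r in rows}
        ok = len(chars) == 1 and not chars & {"-", "N"}
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, length))
    return runs


def _thin(cands: list, cap: int) -> list:
    """Evenly subsample a candidate list down to ``cap`` (deterministic)."""
    if len(cands) <= cap:
        return cands
    step = len(cands) / cap
    return [cands[int(i * step)] for i in range(cap)]


def _unique_in_all(primer: str, ungapped: list[str]) -> bool:
    rc = reverse_complement(primer)
    return all(s.count(primer) + s.count(rc) == 1 for s in ungapped)


def propose_primers(
    alignment: dict[str, str],
    target_region: str = "",
    core: tuple[int, int] | None = None,
    product_range: tuple[int, int] = (400, 1300),
    tm_tolerance: float = 2.0,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Primer pairs bracketing the variable core of a hotspot alignment.

    Candidate windows are conserved, gap-free runs of at least 18 columns;
    the default core is the interval from the first to the last
    non-conserved column. Pairs must amplify a product within
    ``product_range`` in the first genome and have Tm within
    ``tm_tolerance`` of each other; they are ranked by Tm balance, then
    product size. Primers are required to occur exactly once per genome
    within the region.
    """
    rows = list(alignment.values())
    keys = list(alignment)
    if not rows:
        return []
    runs = _conserved_runs(rows)
    if core is None:
        conserved = set()
        for a, b in runs:
            conserved.update(range(a, b))
        variable = [i for i in range(len(rows[0])) if i not in conserved]
        if not variable:
            raise ValueError("no variable core: supply one explicitly")
        core = (variable[0], variable[-1] + 1)

    consensus = rows[0]
    ungapped = [r.replace("-", "") for r in rows]
    left_runs = [(a, min(b, core[0])) for a, b in runs if a < core[0]]
    right_runs = [(max(a, core[1]), b) for a, b in runs if b > core[1]]
    left_runs = [(a, b) for a, b in left_runs if b - a >= MIN_PRIMER_LEN]
    right_runs = [(a, b) for a, b in right_runs if b - a >= MIN_PRIMER_LEN]
    if not left_runs or not right_runs:
        side = "left" if not left_runs else "right"
        warnings.warn(
            f"{target_region or 'region'}: no conserved >= {MIN_PRIMER_LEN} bp "
            f"window on the {side} side of the variable core"
        )
        return []

    def candidates(run_list):
        out = []
        for a, b in run_list:
            for s in range(a, b - MIN_PRIMER_LEN + 1):
                for ln in range(MIN_PRIMER_LEN, MAX_PRIMER_LEN + 1):
                    if s + ln > b:
                        break
                    p = consensus[s : s + ln]
                    try:
                        tm = primer_tm(p)
                    except ValueError:
                        continue
                    out.append((s, s + ln, p, tm))
        return out

    fwd_cands = _thin(candidates(left_runs), 300)
    rev_cands = _thin(candidates(right_runs), 300)

    # prefix counts of non-gap characters per row for O(1) product sizes
    prefix: dict[str, list[int]] = {}
    for g, row in alignment.items():
        acc = [0]
        for ch in row:
            acc.append(acc[-1] + (ch != "-"))
        prefix[g] = acc

    def ungapped_product(g: str, start: int, end: int) -> int:
        return prefix[g][end] - prefix[g][start]

    pairs: list[PrimerPair] = []
    seen: set[tuple[str, str]] = set()
    scored = []
    ref_key = keys[0]
    for fs, fe, fp, ftm in fwd_cands:
        for rs, re_, rseq_plus, rtm in rev_cands:
            if abs(ftm - rtm) > tm_tolerance:
                continue
            prod_ref = ungapped_product(ref_key, fs, re_)
            if not (product_range[0] <= prod_ref <= product_range[1]):
                continue
            scored.append((abs(ftm - rtm), prod_ref, fs, fe, ftm, rs, re_, rtm))
    scored.sort()
    for dtm, prod_ref, fs, fe, ftm, rs, re_, rtm in scored:
        fp = consensus[fs:fe]
        rp = reverse_complement(consensus[rs:re_])
        if (fp, rp) in seen:
            continue
        if not _unique_in_all(fp, ungapped) or not _unique_in_all(
            reverse_complement(rp), ungapped
        ):
            continue
        seen.add((fp, rp))
        sizes = {g: ungapped_product(g, fs, re_) for g in keys}
        pairs.append(
            PrimerPair(
                forward=fp,
                reverse=rp,
                tm_f=round(ftm, 2),
                tm_r=round(rtm, 2),
                product_size=prod_ref,
                target_region=target_region,
                product_sizes=sizes,
                forward_span=(fs, fe),
                reverse_span=(rs, re_),
            )
        )
        if len(pairs) >= max_pairs:
            break
    return pairs


def hotspot_primers(
    records,
    result,
    context: int = 250,
    product_range: tuple[int, int] = (400, 1300),
    tm_tolerance: float = 2.0,
    max_pairs: int = 1,
) -> list[PrimerPair]:
    """Propose primers around one diversity hotspot.

    The hotspot region is extended by ``context`` bases of flanking genomic
    sequence in every genome (flanks are usually coding, hence conserved),
    the extended group is re-aligned, and the original region becomes the
    explicit variable core that the product must span.

    ``records`` maps genome id to its PlastomeRecord; ``result`` is a
    DiversityResult from the divergence scan.
    """
    from .divergence import align_group

    spans = result.region.spans
    seqs: dict[str, str] = {}
    for g, (s, e) in spans.items():
        rec = records[g]
        n = rec.length
        if e < s:
            e += n
        seqs[g] = "".join(
            rec.sequence[i % n] for i in range(s - context, e + context)
        )
    aln = align_group(seqs)
    ref = next(iter(aln))
    core_len = len(result.region.sequences[ref])
    # map reference base offsets to alignment columns
    cols = [i for i, ch in enumerate(aln[ref]) if ch != "-"]
    core = (cols[context], cols[context + core_len - 1] + 1)
    return propose_primers(
        aln,
        target_region=result.name,
        core=core,
        product_range=product_range,
        tm_tolerance=tm_tolerance,
        max_pairs=max_pairs,
    )


def primer_frame(pairs: list[PrimerPair]) -> pd.DataFrame:
    """Long-format primer table: orientation, primer, tm, target, product."""
    rows = []
    for p in pairs:
        for orient, seq, tm in (("F", p.forward, p.tm_f), ("R", p.reverse, p.tm_r)):
            rows.append(
                {
                    "orientation": orient,
                    "primer": seq,
                    "tm": tm,
                    "target_region": p.target_region,
                    "expected_product_size": p.product_size,
                }
            )
    return pd.DataFrame(rows)
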