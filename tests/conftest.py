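"""Shared fixtures: a small simulated genus and toy annotated records."""

import pytest

from plastokit.plastome_io import GeneFeature, PlastomeRecord
from plastokit.simulate import SimulationSpec, generate_genus

#: compact study conditions used by most simulator-backed tests (a 60 kb
#: quadripartite genome keeps every stage fast while exercising all truths)
SMALL_GENOME = dict(
    genome_length=60_000,
    ir_length=9_000,
    ssc_length=9_000,
    lsc_cds=12,
    lsc_trna=5,
    ssc_cds=6,
    ssc_trna=1,
    ir_cds=1,
    ir_trna=1,
    ir_rrna=2,
    n_hotspots=3,
)


@pytest.fixture(scope="session")
def small_genus():
    """Three-species simulated genus with its truth manifest."""
    spec = SimulationSpec(seed=101, n_species=3, **SMALL_GENOME)
    records, manifest = generate_genus(spec)
    return {r.id: r for r in records}, manifest


@pytest.fixture(scope="session")
def small_genus_partitioned(small_genus):
    """The same genus with detected partitions per species."""
    from plastokit import architecture as arch

    records, manifest = small_genus
    parts = {}
    for gid, rec in records.items():
        ir = arch.detect_inverted_repeat(rec.sequence, min_len=5_000)
        parts[gid] = arch.partition(rec, ir)
    return records, manifest, parts


def make_record(seq, features=(), rec_id="toy", circular=True):
    return PlastomeRecord(
        id=rec_id, sequence=seq, circular=circular, features=list(features)
    )


def feature(name, kind, strand, parts, **kw):
    return GeneFeature(name=name, kind=kind, strand=strand, parts=list(parts), **kw)
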