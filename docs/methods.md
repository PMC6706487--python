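# Methods

This note records how plastokit's procedures are defined, the defaults
that matter, what the synthetic data does and does not emulate, and the
choices made where the design was genuinely open.

## Coordinates and circularity

All internal coordinates are 0-based half-open on the linearized sequence;
GenBank I/O converts to and from the flat file's 1-based inclusive
convention. Records are circular by default — deposited plastomes
linearize at an arbitrary origin — and a feature spanning the origin is a
part `(s, e)` with `s > e`. This makes junction arithmetic exact: a
junction is the index of the first base of the downstream region, so a
gene `[s, e)` with `s < J < e` crosses it by exactly `e − J` bases.

## Inverted-repeat detection and partition

Plastid IRs are large (~25 kb) and near-identical, so detection is exact
matching first: 25-mers of the sequence are matched against 25-mers of its
reverse complement, seeds are extended without gaps, and a mismatch budget
(default 0) can be spent greedily one substitution at a time on whichever
side regains the longer exact run. The longest disjoint pair wins; ties go
to the leftmost start. `min_len` defaults to 10,000 — far above any
background inverted repeat in a ~150 kb genome, far below a real plastid
IR. The detector is validated against an exhaustive O(n²)
dynamic-programming scan on short sequences.

Partition follows the LSC → IRb → SSC → IRa orientation convention: the
longer inter-IR arc is the LSC and IRb is the copy immediately downstream
of it. Equal arcs are legal but flagged; an IR pair leaving no arc is an
error. Genes are assigned to regions by majority of their length, which
makes junction-straddling genes well-defined.

The junction report does not require pseudogene (ψ) annotations: the
nearest *annotated* gene on each side is reported, and a crossing gene's
negative distance equals the length of its pseudogenised copy at the other
IR end whether or not that copy is itself annotated.

## Codon-usage indices

Computed from one spliced CDS per unique gene symbol (IR-duplicated genes
contribute a single copy, matching how published per-genome codon totals
scale with unique CDS length; a flag admits both copies). Stop codons
count toward codon totals and the stop fraction but are excluded from
RSCU families, ENc and CBI. The plastid genetic code (table 11) gives
Wright's class structure: nine 2-fold, one 3-fold (Ile), five 4-fold and
three 6-fold families — the 6-fold families (Leu, Ser, Arg) are kept
whole, not split 2+4, per Wright's original formulation
ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Families with ≤ 1 observation are
dropped from their class mean; a missing 3-fold class is estimated from
the mean of 1/F̄₂ and 1/F̄₄; the result is clamped at 61. Note that F̂ is an
estimator depending on n, so ENc is only asymptotically invariant under
scaling all counts.

CBI follows the standard Bennetzen–Hall definition: 0 = uniform
synonymous usage, 1 = only preferred codons. (Some descriptions in the
comparative literature invert this wording; the standard definition is
used here.) The preferred set defaults to the highest-RSCU codon per
family *of the analysed genome itself* — published analyses often rely on
a fixed, unstated preferred set, so absolute CBI values are comparable
only within one choice of set; the set used is recorded in the output.

## Microsatellite mining and polymorphism

Detection reproduces the MISA conventions for perfect repeats: maximal
runs of a primitive 1–6 bp unit, counted in whole repeats, reported at the
smallest primitive unit meeting its threshold (defaults 10 / 5 / 4 / 3 /
3 / 3 for unit lengths 1–6), with re-reports of a contained run at larger
units suppressed. No imperfect/interrupted repeats: a mononucleotide run
broken by one base is two loci. Adjacent loci within 100 bp (MISA's
default) merge into compound SSRs, labelled `(m1)a;(m2)b` when contiguous
and `(m1)a<g>n(m2)b` when separated by g bases. The strand-symmetric motif
class is written `motif/r`, where r is the lexicographically smallest
rotation of the motif's reverse complement — this reproduces conventional
labels such as `C/G`, `AT/AT`, `AATCT/AGATT`.

Cross-genome homology uses fixed-length flank anchors rather than
whole-genome alignment: each locus is keyed by 20 bp of flanking sequence
per side, and loci match across genomes when both flanks reach 80 %
ungapped identity (best match wins; each target locus matches at most
once). A group present in every genome is polymorphic when members differ
in span length or motif composition. The 80 % / 20 bp choice is this
package's explicit parameterisation of "positioned at homologous regions";
both knobs are exposed in the pipeline config because published
polymorphic counts can be sensitive to them.

## Non-coding diversity and hotspots

Intergenic spacers are the maximal intervals not covered by any gene
block, named `geneA-geneB` (order-normalized when grouping); introns are
inter-part gaps of multi-part genes, named `gene.intronK`. Exon clusters
more than 20 kb apart are treated as separate blocks — that is what makes
the trans-spliced *rps12* arrangement behave: its distant 5′ exon does not
swallow the spacers between. Regions must be strictly longer than 200 bp.
Groups present in every genome are aligned by a deterministic star
scheme: every sequence is globally aligned to the first (match +2,
mismatch −1, gap open −5, gap extend −1, via Biopython's pairwise
aligner), and insertions relative to the reference are merged into a
shared gap pattern, joining in order of decreasing identity to the
reference. Identical groups skip alignment entirely. Pre-aligned input is
accepted by calling `nucleotide_diversity` directly.

π is Nei's average pairwise proportion of differing sites with *complete
deletion*: any column holding a gap or N in any sequence is excluded,
mirroring the default of the standard DNA-polymorphism software. For two
sequences π reduces to the p-distance on used sites. Hotspots are ranked
by π (ties broken by name); the report keeps the top k (default 10) and
the subset with π > 0.01.

Which genomes enter a cross-genus scan is an explicit config list
(`representatives`), because a "randomly picked representative per genus"
is not reproducible otherwise.

## Primer proposal

Candidate windows are runs of ≥ 18 alignment columns with zero variation
and no gaps; the hotspot helper extends each region with 250 bp of
flanking genomic context per side (usually coding, hence conserved) and
passes the region itself as the explicit variable core. Primers are 18–24
nt, must occur exactly once per genome within the amplified region, and
pairs must bracket the core with a product in 400–1,300 bp by default
(mirroring the size range conventional for barcode amplicons). Melting
temperature is the simple GC formula Tm = 64.9 + 41·(GC − 16.4)/N, stated
in the output; no hairpin/dimer/salt thermodynamics are attempted, so
published Tm values from full thermodynamic engines are not reproduced.
Pairs are ranked by Tm balance (≤ 2 °C difference), then product size.
Per-genome product sizes are reported individually, since indel variation
makes a single "expected size" ill-defined across species.

## The synthetic genus

The simulator emulates the data model of a sequenced plastome genus: an
ancestral circular genome is assembled from explicit segments — spacers,
gene exons and introns (CDS with start/stop codons, tRNA- and rRNA-sized
RNA genes, IR-resident genes, optional junction-crossing or
junction-gapped genes, one gene with an ACG start), planted simple and
compound SSRs — laid out as LSC + IRb + SSC with IRa appended as the exact
reverse complement of IRb. Species are independent draws from the
ancestor (a star phylogeny): per-segment point substitutions at the
region's rate, and per-species repeat counts for polymorphic SSRs. IRa is
rebuilt from the mutated IRb, so the IR copies evolve in concert and stay
identical, as they effectively do in real plastomes.

Defaults are plastome-like: 150 kb genome, 24.5 kb IR, 17.5 kb SSC;
background non-coding substitution probability 0.002 per site per branch,
hotspots (5 LSC spacers) at 0.02, coding at 0.0005; a stock panel of 12
polymorphic and 6 monomorphic SSR loci spanning all six unit lengths,
IGS/intron/CDS placements and a compound locus. Under the star model the
expected pairwise difference per site is 2θ − (4/3)θ², which the measured
background π matches.

Three constructions make the truth manifest *exact* rather than
approximate:

- guard bases fixed at every region edge (and at SSR boundaries) prevent
  the planted IR and the planted repeats from extending by chance, so IR
  detection returns the planted intervals and every SSR span verbatim;
- background repeats — whether present in the random ancestor or created
  by substitutions — are detected and broken by deterministic single-base
  edits (mirrored between IR copies), so the SSR detector reports exactly
  the planted panel;
- start/stop codons, guards and planted spans are excluded from mutation.

Per-species genome length equals the nominal `genome_length` minus that
species' SSR allele-length deficit (the species with maximal alleles
attains it exactly); IR length is always exact. Same seed, byte-identical
output; species RNG streams are derived as `(seed, 7919 + index)`.

What the synthetic data does **not** emulate — and hence what passing
tests do not show about real data: indels and rearrangements (alignment
columns are never mis-homologised), phylogenetic structure beyond a star,
rate heterogeneity within a region, codon bias (simulated CDS draw sense
codons uniformly, so ENc ≈ 61 by construction), realistic gene counts or
names, IR expansion/contraction polymorphism within a genus, and
sequencing/annotation error. Tests against the planted truth validate the
*algorithms*; the published-genome reproduction tests (which require the
deposited records as local files) validate behaviour on real annotation
quirks.

## Numerical and edge-case choices

- GC fraction excludes N from numerator and denominator; all-N input is
  an error, as are empty sequences.
- Unobserved codon families have no RSCU (absent, not 0); an empty class
  other than the 3-fold makes ENc undefined (error), as does a degenerate
  CBI denominator.
- Ties: IR detection → leftmost pair; preferred codons → alphabetically
  first among maximal RSCU; hotspot ranking → region name; junction
  nearest-gene → gene name.
- A CDS whose length is not a multiple of 3, or with an internal stop, is
  kept with a recorded warning (annotation quirks are data, not errors).
- The pipeline is deterministic end to end: identical inputs and config
  give bit-identical TSV outputs.

## Known limitations

- IR detection assumes the linearization does not split an IR copy across
  the origin (true of conventionally deposited plastomes and of the
  simulator's layout).
- The star-merge aligner is optimal per pair but not globally; for highly
  indel-rich regions an external MSA can be supplied and scored directly.
- Flank-anchored SSR homology can miss loci whose flanks diverge beyond
  the identity cutoff or that transpose between regions.
- Tm is a length-and-GC summary only; candidate primers should be
  re-screened with a thermodynamic tool before synthesis.
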