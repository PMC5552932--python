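# Methods

This note records the models, parameter choices and numerical conventions
behind `ncyc`, and what the synthetic benchmarks do and do not demonstrate.

## Pipeline model

The pipeline treats marker-gene profiling as five successive decision
stages, each with explicit, configurable thresholds.

**Read QC.** A read is kept iff its length is strictly greater than
`min_read_len_exclusive` (default 100 nt, so 101 nt is the shortest kept
read). The strict inequality is the literal reading of a ">100 nt" rule;
`inclusive=True` relaxes it to ≥ for sensitivity analysis. No
quality-based trimming is modeled. Mean kept length is reported half-even
rounded to two decimals.

**SSU recruitment.** The read mapper scores local alignments with match
+1, mismatch −2, gap-in-read −3 per base and gap-in-reference −3 per base.
The stated costs are per-operation, with no open/extend split, so gaps are
linear rather than affine. A mapping is accepted when (read bases inside
the alignment)/(read length) ≥ 0.5 and (identities)/(aligned columns,
gaps included) ≥ 0.8 — i.e. "similarity fraction" is identity over aligned
columns, the mapping-tool convention. Candidates are ranked by raw score
with ties broken by reference id (forward strand first), and the best
*acceptable* candidate wins. Mapped reads are confirmed by a nucleotide
similarity search against the same reference (match +2, mismatch −3, gap
open 5, extend 2; λ = 0.625, K = 0.41; E ≤ 10⁻⁶, read as 1×10⁻⁶); the
confirmed best hit takes precedence over the mapping hit and contributes
the assigned lineage. Tree placement is deliberately replaced by best-hit
lineage assignment (optionally a strict LCA over hits within 1% of the top
bit score); this is a method substitution — it cannot create novel inner
placements the way phylogenetic insertion can, and assignments are only as
fine-grained as the reference taxonomy.

**Translated search.** Full Smith–Waterman (no seeding heuristic) of all
six frames against every subject, BLOSUM62 with affine gaps (open 11,
extend 1; a gap of length L costs 11 + L). Stops translate to `*` and
score −10⁴ against everything, so optimal local alignments never cross a
stop codon; codons containing N translate to X. Genetic code 11
(bacterial/archaeal) is the default since the targets are prokaryotic.
λ = 0.267 and K = 0.041 are the standard gapped BLOSUM62 parameters, held
fixed rather than recomputed per composition, with m = translated frame
length and n = total database residues — the simplest published
convention, so results are reproducible bit for bit. One hit per
(read, subject) is reported: the best-scoring frame. An optional exact
k-mer prefilter (k = 5 amino acids) skips subjects sharing no k-mer with
any frame; it is off by default in the search functions (exactness of the
default path is worth more than speed at desk scale) and enabled in the
large simulation drivers, where planted reads always share k-mers with
their sources, so measured results are unchanged while background reads
skip almost all subjects.

**BSR curation.** Ratio orientation is curated/background, so true
positives sit at ≈1 and false positives below; cutoffs then live in
(0, 1], default 0.8 per family. The per-gene cutoff table of the original
analyses is not public, so cutoffs are configuration with a documented
default rather than constants. Reads with no background hit keep ratio 1.0
and are flagged: absence of a better generalist hit is no evidence of a
false positive. Because the synthetic background database is constructed
as a strict superset of the curated one and both searches share one
scoring scheme, BSR ≤ 1 holds by construction and noiseless curated-source
reads reach exactly 1.

**LCA.** "LCA percent 50" is implemented as weighted-coverage LCA: the
read goes to the deepest node whose subtree covers ≥ 50% of the retained
hits, found by walking down from the root while exactly one child reaches
the threshold; if two children qualify simultaneously (possible only at
exactly 50%), the walk stops at their parent. With lca_percent = 100 this
reduces to the strict path-intersection LCA. MEGAN versions differ in the
exact semantics; both the percentage and strict mode are configurable.
The min-support filter counts a taxon's whole subtree, so promoted reads
come to rest in the first sufficiently supported ancestor; min support 1
(the default) is a no-op, as is max support percent 0.0. min_complexity
is accepted for config compatibility, warned about if non-zero, and
ignored. The napA/narG split is resolved by the gene-family labels carried
on curated references rather than an external orthology database — the
effect is identical when the curated database is correctly labeled.

**Quantification.** nrc = count·10⁹/(total·mean gene length in nt), with
the averaging set for "mean gene length" being the gene family's curated
references (configurable; the choice matters if reference length is
biased relative to the environmental population). Counts entering nrc are
post-curation counts. Proportional-distribution tables divide each
family's nrc by the summed nrc of all analyzed families plus 16S.
Marker-to-16S ratios with a zero denominator are reported as missing, not
errors. Identity breakdowns report integer percentage shares via largest
remainder (summing exactly to 100) and whole-percent identity ranges.

## Synthetic communities

`make_reference_sets` builds each marker family from a random ancestor
protein (family-specific lengths, 150–420 aa — within a factor ~2 of the
real genes, compressed to keep full Smith–Waterman affordable), with
members at 20% within-family divergence and realistic four-rank lineages
echoing the taxa reported for each gene. Decoys are family members mutated
at a per-residue divergence of 0.7 (default) and labeled background; the
background set additionally contains every curated protein and unrelated
random proteins. SSU references are 1200-nt sequences at ~12% divergence
within a domain and ~25% between domains, spanning Bacteria, Archaea and
Eukaryota.

Reads emulate the Ion Torrent regime: truncated-normal lengths (mean 290,
sd 60, minimum 30 nt), uniform fragment positions and strands, constant
Q25 qualities, substitution rate 0.005/base and indel rate 0.008/base with
a 3× multiplier inside homopolymer runs — indel-dominated noise totalling
~1.3%, the platform's characteristic error profile at a desk-scale
approximation. Abundances are realized by largest-remainder quotas so
planted counts are exact (`multinomial=True` restores sampling noise).

The default three-zone study plants marker fractions proportional to the
per-zone reported nrc values times gene length, scaled so the richest zone
carries 6% marker reads — orders of magnitude above real sediment, chosen
so desk-scale samples of a few thousand reads have measurable counts. SSU
is 8% of reads with per-zone domain compositions following the observed
depth gradient, and the planted MG-I share is derived from the observed
amoA : MG-I ratios (2, 2, 0.3), making those ratios a recoverable
mechanism check.

What passing these benchmarks does *not* show: performance on real
metagenomes with sequencing chimeras, conserved-domain sharing between
genuinely homologous families (our families are unrelated random
ancestors, so cross-family confusion is easier than in nature),
composition-biased score statistics, or reference databases that are
incomplete relative to the community. The curation sensitivity/precision
figures are therefore upper bounds specific to the planted design.

## Numerical conventions

* Alignment traceback ties resolve diagonal > up > left; subject-order
  ties resolve lexicographically by reference id everywhere.
* Hit tables are the standard 12-column tabular dialect, 1-based inclusive
  coordinates, reverse-strand hits with qstart > qend; ordering is (query,
  descending bit score, subject), so runs are diffable.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  (spec, seed) pairs give byte-identical FASTQ and truth tables.
* Empty inputs: QC of zero reads reports a missing mean; an empty hit list
  writes an empty file; an empty database raises immediately.
* Problem sizes in the shipped test-suite and acceptance driver (10,000
  reads for the curation benchmarks, 20 × 1,200 reads for abundance
  recovery, 8,000 reads per zone in the acceptance script) were chosen as
  the package's standard desk-scale study conditions; the generators are
  size-agnostic.

## Known limitations

* Karlin–Altschul parameters are fixed constants; E-values for short
  frames near the cutoff are approximate (edge effects are not corrected).
* The LCA operates on the lineage-path taxonomy induced by the reference
  tables, not the full NCBI taxonomy; identically named taxa under
  different parents are kept distinct by keying nodes on full paths.
* The read mapper's acceptance fractions are evaluated on the single best
  traceback; co-optimal alignments with different column compositions are
  not enumerated.
* `hzsA` amplicon-style analyses (PCR primer simulation, clone libraries)
  are out of scope; the gene is treated like every other marker family.
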