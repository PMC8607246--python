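# Methods

This note documents the models, conventions and design choices behind
`somaticfunnel`, in the spirit of a statistical-software methods appendix.
Everything stated here is computed by the test suite or the acceptance
script; nothing is asserted beyond what the code demonstrates.

## Variant model and normalization

Variants are held in VCF coordinates: 1-based, inclusive, `pos` at the
first REF base. Multi-allelic records are decomposed one ALT per variant
before anything else happens. Left-normalization follows the standard
variant-tools algorithm: (a) while REF and ALT share a trailing base and
truncation would not empty both, drop it, extending one reference base to
the left (decrementing `pos`) whenever an allele empties; (b) trim shared
leading bases while both alleles keep length ≥ 2. The result is the unique
left-aligned parsimonious representation; SNVs are fixed points and the map
is idempotent. Symbolic (`<DEL>`), breakend and N-containing alleles are
passed through unchanged with a logged warning rather than dropped.

The identity key is `(chrom, pos, ref, alt)` of the normalized variant;
sample and genotype fields never participate. Requesting a key for a
detectably un-normalized variant is an error — this is what makes all
downstream set algebra (germline subtraction, catalogue filtering,
concordance) well defined. The unit suite cross-checks the normalizer two
independent ways: against a sequence-diff oracle (build the alternate
haplotype, strip common suffix then prefix) on 1,000+ randomized
homopolymer indels, and against `bcftools norm` on a small fixture.

Chromosome names are compared verbatim (no `chr` stripping). The quality
gate — total depth > 50, variant-supporting reads > 15, caller p < 0.01 —
is a load-time predicate, on by default; records missing those metrics pass
with a warning so that minimal fixtures remain usable.

## QC metrics

Ti/Tv counts transitions (A↔G, C↔T) and transversions over SNVs only;
multi-nucleotide substitutions and indels are excluded (they have no
defined transition status) but appear in the type counts. Zero
transversions yields an explicit "undefined" rather than infinity. dbSNP
concordance uses *all* loaded variants in the denominator, not only SNVs.
A variant is on-target when its first REF base lies inside a capture
interval; BED input is 0-based half-open and converted on read.

## Transcript annotation

Transcript models carry genomic exon intervals plus the spliced CDS in
mRNA orientation; minus-strand models reverse-complement alleles before
CDS mapping. Region classes resolve across transcripts by the precedence
`exonic = splicing > UTR5 = UTR3 > intronic > upstream = downstream >
intergenic`; the genes reported are those of every transcript achieving
the winning class, which makes the resolution independent of transcript
input order. Two declared defaults that the underlying study conditions do
not pin down: the splicing window is ±2 bp into the intron (the canonical
donor/acceptor dinucleotides) and up-/downstream extend 1 kb from the
transcript ends. Both are keyword arguments.

Coding consequences are computed from first principles: CDS position by
summing spliced offsets, codon index ⌈cds_pos/3⌉, standard genetic code,
stop written as `X`. Kinds are synonymous/nonsynonymous SNV, stopgain,
stoploss (reference codon is a stop, alternate is not), and
frame-preserving vs frameshift insertions/deletions by `|Δlength| mod 3`.
c. strings use the compact annotator dialect (`c.G689T`); strict HGVS
(`c.689G>T`) is carried alongside. Protein strings for frameshifts are
abbreviated (`p.K12fs`) rather than full-extension HGVS — a deliberate
simplification, since gene- and kind-level downstream logic never consumes
them.

## The funnel

Germline subtraction is purely set-algebraic on normalized keys — no
allele-frequency or likelihood model — mirroring how matched-normal
filtering is done when a statistical somatic caller is not in play. The
subtraction refuses to run when both inputs carry the identical sample
label, a cheap guard against swapped arguments. "Passing" a novelty
catalogue means being *absent* from it; the cascade applies the catalogues
in a configured order, records survivors after each, and the final novel
set is provably order-independent (the intermediate counts are not).
Catalogue matching is allele-exact on normalized keys; locus-level
matching is intentionally not the default.

A variant counts as synonymous (and is dropped) only if every overlapping
transcript calls it synonymous. The functional SNV/other split counts
nonsynonymous SNVs, stopgains and stoplosses as SNVs and indels as others.
Gene extraction takes the union of symbols over functional variants
(multi-gene variants contribute all symbols), uppercased on load; the CGC
comparison reports the intersection, per-tier counts and the Tier-1
percentage rounded to one decimal. Pathway analysis accepts an optional
explicit gene-subset input rather than deriving one, for workflows where
the enrichment query is curated separately from the extracted gene set.

## Over-representation analysis

Counting is gene-level throughout: n = |query ∩ universe|, K = |pathway ∩
universe|, k = |query ∩ pathway ∩ universe|, p = P(X ≥ k) with X ~
Binomial(n, K/N) computed via the regularized survival function (verified
against direct pmf summation to ≤ 1e-12 up to n = 500). Only pathways with
k ≥ 1 enter the BH correction, matching the "hit by at least one gene"
reporting convention; ties in p are ordered by pathway id for
deterministic output. Entity-level expansion as performed by pathway web
servers (where one gene maps to several physical entities) is out of
scope, which is why server-reported p-values are not comparable
quantities here.

## Consensus pathogenicity

Predictor verdicts normalize via a fixed vocabulary: SIFT
deleterious/tolerated, PolyPhen-2 probably- and possibly-damaging vs
benign, MutationTaster disease_causing vs polymorphism, PROVEAN
deleterious vs neutral; anything unrecognized is `unknown`.
`possibly_damaging` counts as damaging — a declared, configurable choice.
A variant is unanimously damaging only when every supplied method says
damaging with no unknowns. Predictor scores are consumed as data; the
predictors themselves are never re-implemented.

## Dose–response fitting

Responses are percentages of the averaged DMSO (vehicle) control;
concentrations are micromolar throughout (the screen's IC₅₀ table prints
unitless values; micromolar is the documented assumption). The 4PL model
is parameterized as

    y(x) = bottom + (top − bottom) / (1 + 10^((log10(IC50) − x) · hill)),

so hill < 0 gives the descending viability curve of an inhibitor and the
fitted curve always passes through (top+bottom)/2 at x = log₁₀IC₅₀.
Estimation proceeds in three stages: ordinary least squares from
(top = max y, bottom = min y, hill = −1, log IC₅₀ = median x); iterative
reweighting with σᵢ ∝ fitted value, appropriate because luminescence noise
is multiplicative (constant CV); and a final Nelder–Mead polish of the
exact profile likelihood for that noise model, which carries a Σ log f
term the reweighting omits. The polish is skipped on (numerically)
noiseless data, where that likelihood degenerates. On failure the fit
restarts from jittered initials and, failing that, returns best-effort
parameters flagged unconverged; flat (dose-independent) data are rejected
outright. Parameters are unconstrained — the hill sign is left to the
data.

A Cramér–Rao analysis of the fixture design (8-point half-log series,
triplicate, 5% CV noise) puts the floor at ≈4.5% median relative IC₅₀
error, so the recovery study's ≤5% bar is met only by the efficient
estimator; this is why the weighted/MLE path is the default rather than an
option.

## Synthetic cohorts: what they emulate, and what they do not

`FunnelProfile` states the planted composition — totals, shared germline,
catalogue-known, novel split into non-coding / synonymous / functional
SNV / functional indel, gene multiplicities, CGC overlap — and validates
its internal identities before any generation. The default profile is the
study condition: 32,917 / 30,939 total calls funneling to 983 novel, 491
functional in 423 genes, 21 CGC-common (19 Tier 1). The generator plants
variants so the pipeline must reproduce each count *exactly*, and the test
suite additionally requires exact set equality between recovered and
planted novel-functional variants.

Fixture geometry: four named transcripts (CSF2RB-like `NM_000395` with
codon 230 = AGC at CDS 688–690 across 6 exons, plus KCNQ3-, NRCAM- and
SCN11A-like models) carry the published coding changes c.G689T/p.S230I,
c.A293G/p.Q98R, c.C4G/p.Q2E and c.A3253C/p.K1085Q; generic genes (about a
seventh on the minus strand) hold the remaining exonic variants; a
"variant farm" contig holds background calls in 24-bp slots, giving every
variant a collision-free canonical key by construction. Indels are planted
in carved homopolymer runs and a fixed fraction are deliberately spelled
right-shifted in the tumor VCF (while the normal VCF carries the
left-aligned spelling), so germline subtraction succeeds only if
normalization is correct. Caller metrics are drawn to pass the default
quality gate; alternate alleles are transition-biased 2:1 for realism.
Exonic indels go to plus-strand genes only; strand handling of the
consequence engine is exercised by dedicated mirror-fixture tests instead.
The master seed defaults to 230 (the mutated codon number — arbitrary but
memorable); identical seeds give byte-identical artifacts.

What the fixtures do **not** emulate: read-level data (no FASTQ/BAM, no
sequencing-error or coverage model), allele-frequency structure,
linkage, realistic inter-variant spacing, population-genetic site-frequency
spectra, or entity-level pathway membership. Passing tests therefore
demonstrate the correctness of the *filtering, annotation and statistical
machinery*, not performance on raw sequencing artifacts upstream of the
VCF.

Standalone QC fixtures pin the metric arithmetic: a substitution set with
A>G 700, G>A 650, C>T 720, T>C 630 plus 125 of each transversion type
(Ti/Tv = 2.7 exactly), and a 1,000-variant set with 962 keys planted in a
mock dbSNP (concordance 96.2%). The pathway fixture provides a
13,870-gene universe, a 309-gene query with exactly 178 in the universe,
and 900 pathways of which exactly 695 are hit, including small named
pathways (sizes 33, 8, 8, 9, 52, 13, 53, 32, 2, 2) mirroring the top-hit
table structure. The dose–response fixture plants IC₅₀ = 0.94 µM,
hill = −1, top = 100, bottom = 5 on a 20 µM-anchored half-log series
(anchor chosen to minimize var(log IC₅₀) at the fixture IC₅₀), triplicate
wells with 5% multiplicative Gaussian noise and six DMSO wells.

The non-exonic novel calls (novel − exonic) are split round-robin across
intronic, splicing, 5'UTR and 3'UTR placements — the underlying class
breakdown is not constrained beyond "non-exonic", so a uniform split is
used.

## Problem sizes in the test suite

The end-to-end suite runs the full default cohort (~63,900 calls across
both samples) once as a shared fixture — generation plus the complete
funnel takes a few seconds — and uses a proportionally scaled profile
(1,578 / 1,400 calls, same identities: 60 novel, 34 functional, 28 genes)
where many independent cohorts are needed, e.g. the ten-seed
planted-truth-recovery check and CLI tests. The IC₅₀ recovery study runs
200 replicates at replicate seeds 0–199.

## Known limitations

- Region classification and target membership use the variant's first REF
  base; a long deletion straddling a boundary is classified by its anchor.
- Frameshift/insertion protein strings are abbreviated, not full HGVS.
- Consequences are reported per transcript with no canonical-transcript
  selection; the fixtures have one transcript per gene, so downstream
  counts are unaffected there.
- The binomial ORA treats genes as exchangeable units; no gene-length or
  coverage bias correction, no pathway-topology-aware correction.
- The germline subtraction has no contamination or tumor-in-normal model;
  a real low-purity pair would need a statistical somatic caller upstream.
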