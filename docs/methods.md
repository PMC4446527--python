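# Methods

This note documents the models, parameter choices and numerical decisions
behind `cenphase`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate conventions

All coordinates are 0-based half-open internally. bedGraph and BED files
are written 0-based half-open as those formats require; TSV tables and
human-readable reports print 1-based inclusive positions, the convention
genome browsers use. `GenomicInterval` converts losslessly in both
directions.

## Synthetic data model (`simulate`)

The generator emulates a CENP-A ChIP-on-chip study of a satellite-free
centromere in a diploid cohort. Defaults encode the study design:

| parameter | default | meaning |
|---|---|---|
| region | chr11:25,566,599–28,305,611 | tiling-array region (~2.74 Mb) |
| probe_spacing | 100 bp | array resolution |
| domain_width_range | 80–160 kb | per-homolog CENP-A domain width |
| placement_window | chr11:27.40–27.90 Mb | ~500 kb window containing all domains |
| enrichment_amplitude | 1.5 log2 | probe ratio over a singly-bound locus |
| noise_sd | 0.3 log2 | probe noise (a generator choice; the array's true noise is not published) |
| snp_density | 1/10 kb | informative heterozygous markers |
| input_depth, ip_depth | 200 | allele counts per marker and sample |
| mono_ip_fraction | 0.95 | IP fraction of the bound homolog's allele |
| boundary_jitter | ±5 kb | per-edge jitter when an individual inherits a pool epiallele |

**Occupancy model.** A probe's expected log2 ratio is 0 where no homolog
is bound, `amplitude` where one is, and `amplitude + 1` where both are:
IP yield is proportional to bound-copy count, so two bound copies double
the immunoprecipitated DNA (one extra log2 unit), they do not double the
log ratio.

**Allele skew.** Input allele counts are Binomial(depth, 0.5). At a
marker inside exactly one homolog's domain, the IP fraction of that
homolog's allele is `mono_ip_fraction` (0.95, not 1.0 — antibody
background carries some unbound chromatin); where neither or both
homologs are bound it is 0.5. Which allele label sits on which homolog is
random per marker, as in real data, so allele labels carry no haplotype
information.

**Marker placement** is a regular grid at 1/`snp_density` spacing with a
random per-individual offset: the study design seeks informative
heterozygous positions across the whole region deliberately, so coverage
is not a Poisson scatter. A consequence used by the recovery analyses:
any interval of length ≥ 2×spacing contains at least two markers.

**Domain-pair geometry.** Each individual's two domains form one of the
two configurations observed in the emulated cohort: clearly separated
(gap ≥ 30 kb pre-jitter) or partially overlapping with a resolvable
shared centre (overlap ≥ 20 kb, reciprocal overlap ≤ 0.30). Geometries
below probe/marker resolution — domains separated or overlapping by a
few kb — exist in principle but are excluded from the default
conditions; the phaser cannot distinguish them from a single domain and
would flag or misclassify such individuals (see Limitations).

**Epiallele pools.** `simulate_cohort` tiles `pool_size` distinct
intervals across the placement window (even anchors, random widths and
jitter), enforcing pairwise reciprocal overlap ≤ 0.55 — well below the
0.7 identity threshold even after inheritance jitter. Every pool member
is assigned to at least one individual, so the planted distinct count is
recoverable. `PUBLISHED_EPIALLELE_LAYOUT` + `PUBLISHED_ASSIGNMENT` are a
stylised seven-epiallele layout reproducing the observed cohort's sharing
and overlap structure (separated pairs for three individuals, partially
overlapping pairs for two); the coordinates are synthetic, not measured
positions.

**qPCR and fibres.** qPCR Ct values derive from a perfect-doubling
baseline with the fold enrichment at the amplicon midpoint
(`fold_single` per bound homolog, 1 outside); triplicates and 1:1/1:10/
1:100 standard curves are attached, all with the same per-well Gaussian
Ct noise. Fibres sample one homolog uniformly and report the CENP-A
(CREST) and BAC intervals in fibre-local coordinates under a shared
multiplicative stretch factor.

All randomness descends from one root seed through named
`numpy.random.SeedSequence` child streams (placement, probes, markers,
qPCR, fibres), so sub-experiments are individually reproducible.

## Peak calling (`peakcall`)

The threshold is the q-th percentile (linear interpolation) of all probe
ratios of one track — per individual, since each array has its own signal
distribution. A probe exceeds it by chance with p = 1 − q/100, so a run
of r consecutive supra-threshold probes has chance probability p^r; the
minimum significant run is the smallest r with p^r ≤ α (r = 3 at the
default q=98, α=1e-4). Comparison is strictly greater, which makes a
constant track degenerate-safe (threshold equals the constant, nothing
exceeds it).

**Seed-and-extend.** Maximal supra-threshold runs of any length chain
into clusters when separated by ≤ `max_gap_bp`; a cluster is a peak only
if it contains at least one significant run. The seed requirement gives
the same chance-discovery control as the plain run-length rule
(~n·p³ expected false peaks per track, ≈0.2 for 27,000 probes). Chaining
matters because the bound domains here occupy 5–12% of the array — more
than the top-(100−q)% budget — so the global percentile sits *inside*
the enriched signal and only a thinned, spatially random subsample of
domain probes exceeds it. Chaining across short gaps reassembles the
domain; without it every domain fragments. `max_gap_bp` defaults to
10 kb (100 probes): in the singly-bound flanks of a partially
overlapping domain pair the supra-probe density can drop to ~0.1, where
50-probe gaps occur about once per track but 100-probe gaps are ~100×
rarer. Reported peak boundaries extend half the median probe spacing
beyond the boundary probes, since each probe represents a ~100 bp
window.

Raising q at fixed α does not monotonically shrink peak coverage,
because the minimum run length itself drops (3 → 2 between q=98 and
q=99 at α=1e-4); monotonicity holds, and is tested, at matched run
length.

## Marker classification and phasing (`snp_phase`)

A marker must first look heterozygous in input: an exact two-sided
binomial test against 0.5 not rejected at α and input minor fraction
≥ 0.25. Then the IP counts are tested against the *input* allele
fraction (not 0.5, so input skew cancels):

* **monoallelic** — IP major fraction ≥ 0.80 and the exact binomial test
  rejects at α = 0.01;
* **biallelic** — IP major fraction < 0.65;
* **uninformative** — the band [0.65, 0.80), zero IP depth, or failed
  heterozygosity.

The original evidence was Sanger traces judged by eye, so these
quantitative cutoffs are this package's operationalisation; the dead band
avoids overcalling. Sanger trace peak-height ratios can be supplied as
pseudo-counts scaled to a nominal depth (~100). Microsatellites are
classified by the same rule over length-variant counts.

Only the monoallelic/biallelic dichotomy is positional evidence: *which*
allele is enriched depends on arbitrary per-marker allele labelling, so
mono directions are never compared across markers. (With that convention
unavailable, requiring opposite directions at the two edges of a broad
peak would be unenforceable; the pattern matcher therefore accepts any
mono calls at the edges.)

**Smoothing** is one-sided: an isolated monoallelic call inside a
biallelic consensus (≥3 agreeing informative neighbours) is reclassified
— allele dropout and preferential amplification produce spurious
monoallelic reads — but an isolated biallelic call is kept, because
balanced contamination of a truly monoallelic site would require half
the signal to come from the unbound homolog, and a single biallelic
marker can legitimately mark a minimal overlap centre.

**Structure calls.** Two peaks with monoallelic markers in each → one
domain per peak on different homologs (homolog 1 = leftmost; a labelling
convention, since true haplotype linkage across peaks is unknown). Two
peaks biallelic in both → both peaks on both homologs
(`shared_multidomain`, four records). One peak all-monoallelic → a
single domain on one homolog. One peak with the mono⁺ bi⁺ mono⁺ pattern
→ deconvolution: the biallelic segment's boundaries are the midpoints
between the outermost biallelic markers and their flanking monoallelic
markers; homolog 1 spans peak start → segment end, homolog 2 spans
segment start → peak end, and the segment is their overlap. Evidence
matching none of these → `inconsistent`, no domains emitted. More than
two peaks is outside the structures this cohort design produces and is
flagged `unresolved`.

## Epiallele catalogue (`epiallele`)

Domains pooled across individuals are clustered by single linkage under
reciprocal overlap ≥ 0.7. The threshold tolerates inheritance jitter
(±5 kb) plus boundary-estimation error (~1 kb for clean peaks, up to
~7 kb for deconvolved edges quantised to marker midpoints) on 80–160 kb
domains, while separating partially overlapping distinct epialleles
(pool construction keeps those below 0.55). Single linkage lets a chain
of near-identical alleles collapse into one entry, so the count is a
lower bound — consistent with reporting "at least k" distinct
epialleles. Labels name each member by individual letter + a/b homolog
and join shared entries in cohort order (`Da/Eb`).

Fibre patterns: SUPERIMPOSED if ≥ 80% of the CENP-A staining length lies
inside the BAC signal (`cover_floor` 0.8); FLANKING if ≤ 20% overlaps and
the nearest edges are within `gap_tolerance` (10 kb fibre-local, post
stretch-normalisation); PARTIAL between; UNSCORABLE if disjoint beyond
the tolerance. Tallies count the two most frequent scorable patterns and
test the split against 0.5 with an exact two-sided binomial test.

## qPCR (`qpcr`)

Replicates aggregate by arithmetic mean (with the SD reported); ΔCt =
mean Ct_IP − mean Ct_input; ΔΔCt subtracts the control amplicon's ΔCt,
cancelling plate-wide offsets between sample classes; log2 fold = −ΔΔCt
exactly. Efficiency (10^(−1/slope) − 1 from the dilution-series fit) is
QC metadata only — fold estimates are pure 2^−ΔΔCt. A profile is
computed only when every attached standard curve has r² in [0.95, 1]
(inclusive at both ends).

## Sequence composition (`seqcomp`)

GC% excludes N from the denominator; ambiguity codes other than N are
rejected unless explicitly allowed. Repeat-class coverage is the union of
same-class elements (never a sum of lengths) over the region's non-N
length; different classes may overlap each other. RepeatMasker `.out`
(standard 15-column layout, 1-based inclusive) and plain TSV dialects are
both accepted; satellites, simple repeats and unknown classes fall
outside the six analysed classes and are skipped.

The comparison is a two-sided one-sample Student's t of the control
values against the target region's value (df = n−1), the defensible
test when one target region faces many controls; raw p values are
reported without multiple-testing correction. Zero control variance
yields p = 1 if the target equals the control mean, else p = 0, with the
t statistic set accordingly. The implementation is cross-checked in the
tests against a closed-form evaluation of the t distribution through the
regularised incomplete beta function, to 1e-10.

## Problem sizes used by tests and the acceptance script

Recovery analyses use the full-size array (27,391 probes at 100 bp) per
individual: 200 individuals for structure-call recovery, 50 cohorts
(pool sizes cycling 3–9, five individuals each) for end-to-end epiallele
counting, 50 replicates for broad-peak deconvolution, 100 null tracks of
27,000 probes for calibration, and 4,000 replicate plates for ΔΔCt noise
propagation. The composition fixture uses 64 control regions of 50 kb
drawn around a 40.25% GC mean (range clipped to 34.74–48.52%) against a
39.12%-GC target sequence, matching the published control-panel summary
statistics. These sizes keep the whole suite under half a minute while
leaving Monte-Carlo margins (binomial SEs of a few percent) well inside
the asserted thresholds.

## Limitations

* The probe model is flat-topped with iid Gaussian noise; real array
  signal has probe-affinity structure and spatial autocorrelation, which
  the percentile caller implicitly exploits on real data. Passing the
  synthetic recovery tests shows the inference chain is correct under
  the stated model, not that the caller's boundaries are unbiased on
  real hybridisations.
* Domain pairs separated or overlapping by less than probe/marker
  resolution are excluded from the generator's default conditions; on
  real data such configurations would be called as a single domain on
  one homolog.
* A single peak whose markers are all monoallelic cannot distinguish one
  domain from two same-homolog domains merged across a short gap;
  resolving that requires fibre data, which the pipeline treats as
  corroborating rather than primary evidence.
* Homolog labels (1 = leftmost) are consistent within an individual
  only; no statistical haplotype phasing across individuals is
  attempted.
* The fold model in the qPCR simulator places the whole amplicon at its
  midpoint occupancy; amplicons straddling a domain edge are not
  modelled fractionally.
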