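# Methods

This note documents the models, numerical choices and limitations behind
`glycopg`, in the order the pipeline runs.

## Isoform model and ORF policy

A gene is an exon grammar: uniquely identified exons labelled constitutive or
variable, in nucleotide or amino-acid mode, plus transcripts as ordered exon
references. Partial exon usage is expressed with 0-based half-open offsets on
exon-local coordinates and surfaces in junction tags as `(partial)` suffixes
(e.g. `e2(partial)-e3(partial)`), without inventing genomic coordinates.

ORF policy (nucleotide mode): candidate ORFs start at every AUG of the
spliced transcript on the forward strand (transcripts are already stranded
mRNA); translation runs to the first in-frame stop (not emitted) or the end
of the sequence. The transcript's ORF is the longest candidate, earliest
start on ties. `screen_transcript` classifies: `fragment_noncoding` (< 3 nt),
`no_orf` (no AUG), `premature_stop` (longest ORF < `min_orf_aa`), else
`coding`. The default `min_orf_aa = 30` excludes short non-coding transcript
artifacts without encoding anything gene-specific; it is a parameter, not a
biological claim. Scanning all AUGs (rather than only the 5'-most) makes the
verdict a property of the sequence rather than of leader-peptide noise, and
matches a brute-force all-frames ORF scan by construction.

Junction positions are recorded as the 0-based index of the first residue
encoded (even partially) by the downstream exon; a peptide is
junction-diagnostic iff it covers that residue and the one before it. A
junction falling upstream of the ORF start or downstream of the stop is not
peptide-observable and is dropped.

Amino-acid-mode grammars bypass translation and screening entirely (isoform
sequences are taken as given), which is how curated protein-level variant
sets are loaded.

## Mass calculus

Atomic monoisotopic masses come from `pyteomics` (CODATA/IUPAC). Glycosyl
residue formulas: HexNAc C8H13NO5, Hex C6H10O5, dHex C6H10O4, NeuAc
C11H17NO8. Modification deltas are sums of residue masses — strictly
additive and linear in counts (tested to 1e-6 Da).

Permethylated benzyl glycosides: the molecule is glycan + benzyl alcohol
minus one water per bond formed; permethylation methylates every free
hydroxyl (including anomeric), every acetamido NH, and methyl-esterifies the
NeuAc carboxyl. Per free monosaccharide the methylatable-site counts are
Hex 5, HexNAc 5, dHex 4, NeuAc 7; each glycosidic linkage consumes two sites
(donor anomeric + acceptor hydroxyl) and the benzyl consumes the reducing-end
anomeric site, so for n residues `sites = Σ sites_i − 2(n−1) − 1` — a
composition-level quantity independent of linkage or branching, which is why
composition masses cannot distinguish isomers. [M+Na]+ adds the sodium atom
mass minus one electron (0.00055 Da, below the 2 d.p. readout either way,
but kept for correctness).

The HexNAc oxonium series is computed from fragment cation formulas:
C8H14NO5+ (204.087, the trigger ion), C8H12NO4+ (−H2O), C8H10NO3+ (−2H2O),
C6H10NO3+ (144.066), C7H8NO2+ (138.055), C6H8NO2+ (126.055). The
144.066/138.055 intensity ratio is reported per spectrum (GalNAc-type
spectra run high) but never thresholded — no published numeric cutoff
separates GalNAc from GlcNAc robustly.

The sequence-modification catalogue (carbamidomethyl, oxidation,
deamidation, N-terminal formylation/acetylation, pyro-Glu, and the FFPE
oxidative set: Lys→aminoadipic semialdehyde, Arg→glutamic semialdehyde,
Pro→pyroglutamic acid, Trp→hydroxy/N-formyl-kynurenine and kynurenine,
Thr→2-amino-3-ketobutyric acid, Lys methylation, hydroxylation,
carbonylation) ships as a TSV of elemental gain/loss formulas; deltas are
recomputed from formulas at load time and the printed nominal column (which
accepts decimal commas, as some published tables use them) serves only as a
provenance check. Where a circulating nominal value is off by a unit in its
last digit from the elemental arithmetic (e.g. 2×203.0794 = 406.1588 vs
2×m(C8H13NO5) = 406.1587), the elemental value wins.

## Glycome annotation and search space

Annotation libraries enumerate all compositions with HexNAc ≥ 1 (the
O-GalNAc reducing core is always present in the benzyl-reporter readout)
whose permethylated [M+Na]+ falls in the scan range, default 540–2000.
Assignment is nearest-mass within a ppm tolerance, ties broken by smaller
|ppm| then fewer monosaccharides; default tolerance 10 ppm, a realistic
internally calibrated MALDI-reflector figure (the instrument setting is not
a library property, so it is a parameter). Composition labels use trivial
names (Tn, T, STn, core 3, fucosyl-T, sialyl-T, disialyl-T, core 2) only for
compositions with a single dominant structure; anything else keeps its
composition string, because a composition does not determine a structure.

The search space is the annotated glycome plus, optionally, every
progressively NeuAc-stripped form of each observed composition — samples are
sialidase-treated before digestion but de-sialylation can be incomplete, so
both the stripped and residual-sialyl forms must be searchable. Tn (single
HexNAc) is always included. Raw spectrum processing (baseline, centroiding,
calibration) is out of scope; inputs are calibrated centroids.

## Digestion and candidate expansion

Chymotrypsin specificity: cleavage C-terminal to F/Y/W/L, never before Pro —
the dominant high-specificity convention; the residue set is a parameter.
Defaults: ≤2 missed cleavages, peptide length 5–45 (search practicality).
Glycoform expansion assigns 0..3 distinct S/T sites per peptide, each
carrying any composition from the search space, in deterministic
lexicographic order, capped at 10⁴ candidates per peptide with an explicit
truncation flag (never silent). The cap and the 3-site default bound the
combinatorics of Ser/Thr-dense variable-exon peptides, where site density is
exactly what makes these regions hard. Carbamidomethyl-Cys is applied as a
fixed modification when configured.

## Spectral filtering and scoring

The trigger decision is presence of a peak within ±0.01 Da of the HexNAc
oxonium m/z in an HCD scan (presence-only by default; a relative-intensity
floor is available because absolute instrument thresholds are
hardware-specific). Inclusion entries merge precursors within 5 ppm at the
same charge and sort by best evidence intensity; the list is a deterministic
function of the spectrum stream.

Fragment generation: HCD treats O-glycans as labile — the b/y series is
generated both glycan-stripped and glycan-retained (a fragment keeps the
glycans of the sites it contains); CID generates the Y-ion ladder (intact
peptide plus every sub-composition of its glycan, down to Y0) plus the
backbone series; oxonium ions are added for glycosylated candidates; singly
and doubly charged fragments. Matching is presence/absence within a Da
tolerance (defaults 0.02 HCD / 0.6 CID; precursor matching 5 ppm), so scores
are invariant to intensity scaling and peak order.

Score: −log₁₀ P[Binomial(n, p) ≥ k], n theoretical fragments, k distinct
matched, p = 2·tol·n_peaks/span clamped to [1e-9, 0.99]; evaluated via the
log-survival function so deep matches keep resolving below double underflow,
capped at 350. Ties break by fewer occupied glycosites (parsimony), then
lexicographic peptide. A noise peak can only raise p for all candidates
equally, never a single candidate's k.

Decoys are reversed peptides with the C-terminal residue kept (preserving
the enzymatic C-terminus and precursor mass) and sites/mods moved with their
residues; self-reversing sequences are skipped. q-values are the running
minimum of #decoys/#targets down the ranked list (monotone by
construction); at equal scores decoys rank above targets, the conservative
direction. The per-spectrum best match enters FDR estimation — standard
target–decoy competition. This scorer is an open, documented surrogate for
commercial engines whose internals are unpublished; it shares their
inputs/outputs, not their weights.

Site localization: an assignment is localized iff for every isomeric
placement of the same glycans on the peptide's S/T sites, at least one
matched glycan-retained backbone ion is incompatible (no theoretical m/z of
the alternative within tolerance). Single-placement peptides are trivially
localized; assignments without matched site-determining ions are ambiguous
and reported in a separate stratum — ambiguity is an honest output, not an
error.

## Reporting rules

Isoform assignment is conservative: only junction-diagnostic or
isoform-unique peptide evidence assigns (default ≥1 accepted GPSM,
configurable); peptides shared among isoforms contribute to every compatible
isoform's coverage but never to assignment. Coverage is the fraction of
distinct residues of the complete isoform sequence covered by accepted
peptides. A spectra group ("band", free-text metadata — gel electrophoresis
is not modelled) with no accepted GPSM reports "No ID". Outputs are TSV +
JSON with full deterministic ordering (byte-identical across runs).

## Synthetic data: what it emulates and what it does not

The toy grammar has the shape of the CD44 locus: 19 exons — 5 constitutive
N-terminal (e1 opens the ORF), 9 variable (v2–v10, Ser/Thr-dense at 0.35
like the mucin-type variable region, vs 0.10 elsewhere), 5 constitutive
C-terminal (e19 carries the stop). All exon lengths are codon multiples so
any variable subset preserves frame; every 6th residue is a cleavage residue
so digests stay search-scale; sampled codons exclude Met and stops so the
ORF start is unique. Reference transcripts emulate the standard isoform
(producing the diagnostic e5-e15 junction), v2-10, v3-10 and v8-10. The
sequences are synthetic; only the splice topology mimics the real gene.

Spectrum generator: each theoretical fragment is observed with probability
`efficiency` (default 0.7) at log-normal intensity; glycosylated HCD spectra
always carry the full oxonium series with a configurable 144/138 ratio
(default 2.5, GalNAc-like) under mild multiplicative noise; noise peaks are
Poisson-count (λ = 20), uniform in m/z over the scan range, log-normal in
intensity; every emitted m/z is jittered uniformly within ±5 ppm. The noise
model is deliberately the simplest one that exercises false matching of a
presence/absence binomial score. Null spectra park pure noise at real
candidate precursor m/z values, emulating triggered co-isolation junk — any
confident match on them is a false discovery by construction. Determinism:
one `numpy` Generator seeded from the config, single-threaded, stable sorts;
outputs are bit-reproducible per platform/numpy version.

Not emulated: isotope envelopes, peak shapes, chromatography, intensity
structure of real fragmentation, glycan structural isomers, in-source decay.
Passing tests therefore demonstrate correctness of the computational
pipeline under a controlled noise model, not instrument-grade performance on
real data.

## Validation experiment sizes

The test suite's end-to-end experiment searches 4 isoforms digested at ≤2
missed cleavages, expanded over a 3-composition space (Tn, T, sialyl-T —
sialyl-T's stripped ladder) into ~1.5×10⁵ candidates plus reversed decoys;
each of 5 seeds generates 50 glycopeptide spike-ins and 500 null spectra.
Recovery is scored at the peptide + glycan-composition level; site placement
is assessed separately by the localization test, since composition-identical
site isomers are often isobaric in every observed ion when site-determining
fragments are sampled out. Empirical FDR at q ≤ 0.01 is compared against 3%
via a Wilson 95% interval, the resolution such an experiment actually has at
~50 acceptances per seed. Digestion and trigger logic are validated against
brute-force oracles (100 random 200-residue sequences; 1000 spectra).

## Known limitations

* Composition-level glycan identification only; no structure or linkage.
* The binomial score ignores intensities and fragment correlations; it is
  calibrated by decoys, not by an analytical null.
* The q-value estimator is the plain decoy/target ratio (no +1 correction),
  the convention that makes an all-target list q = 0; at very small accepted
  counts it is slightly optimistic, which the Wilson-interval check in the
  validation acknowledges.
* Semi-specific/non-specific digestion and N-glycosylation are out of scope.
* mzML support covers centroided MS2 with 32/64-bit float arrays (zlib or
  uncompressed); MGF is the primary exchange format.
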