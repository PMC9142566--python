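# Methods

This note documents the models behind `twodna`, the defaults that
matter, what the synthetic data does and does not emulate, and the
design choices made where the architecture left room.

## Source coding of images

Quantization maps an 8-bit intensity v to level ⌊v/32⌋ and back to the
bin midpoint 32ℓ+16; only the 3-bit depth is validated, although the
depth is a parameter in principle. The Hilbert order is the standard
recursive construction over the smallest 2^k × 2^k square covering the
image, first cell at (0,0), with out-of-image cells dropped; it is fixed
so that encodings are reproducible byte for byte.

Within one (channel, level) subset, "differential encoding" operates on
pixel *positions* along the curve: values inside a level subset are
constant, so position gaps are the informative differences. Gaps 1–15
are Huffman symbols; larger gaps use an escape symbol followed by a
20-bit literal. The Huffman code is rebuilt per (image, channel, level),
canonical, with deterministic tie-breaking, and serialized as sixteen
5-bit code lengths into one header segment per level stream. Header
segments are the decoding key for their stream, so they are replicated
(default 3 copies, configurable) in the designed pool; data segments are
never replicated.

Each data segment is padded to the 242-bit oligo payload and opens with
a fixed-width absolute anchor (⌈log₂ n_pixels⌉ bits, capped at 20) and
an 8-bit gap count. The anchor realizes stream synchronization: a lost
or corrupt oligo damages only the pixel run its segment claimed, which
is exactly the contiguous block-discoloration phenomenology the
restoration stage is designed for. On decode, pixels claimed by no
surviving segment are flagged *missing* (filled with level 0), pixels
claimed more than once are flagged *conflict* (lowest level wins); both
flags feed the detector as decoder provenance.

## Constrained DNA mapping

Payload blocks use the enumerative code over 13-mers with GC count in
{6,7}, G-runs ≤ 3 and no `GG` at either end (24,535,168 valid words ≥
2²²); addresses use 10-mers with GC in {4,5,6} under the same run rules
(604,896 ≥ 2¹⁶). The per-block GC windows are chosen so that any
concatenation of blocks and compliant primers keeps whole-oligo GC
inside 40–60 %, and the no-`GG`-ends rule guarantees cross-boundary
G-runs ≤ 3 without lookahead. Encoding is rank/unrank by a
transfer-matrix DP over (position, GC so far, current G-run) rather than
a 4.2-million-entry table. An invalid received block decodes to the
nearest valid in-range codeword (ties to the lexicographically smallest)
with a validity flag — never an exception, because the restoration stage
is the error handler. Single substitutions frequently land on another
valid codeword (silent miscoding); this is accepted by design and
surfaces, if at all, as detectable discoloration.

Colour tags are the first lexicographic triple of 3-mers at pairwise
Hamming distance 3 among tags containing no `GG` (`AAA`, `CCC`, `GTG`);
the `GG` exclusion keeps boundary G-runs short. Addresses carry 4 image
bits and 12 segment-index bits; segment 0 of each (channel, level)
stream is its header. Primers are rejection-sampled 20-mers under
combinatorial proxies: GC 40–60 %, G-run ≤ 3, no `GG` ends, pairwise
Hamming distance ≥ 8, and no 3′-terminal 5-nt reverse-complement match
against any primer (primer-dimer proxy). Thermodynamic models are out of
scope.

## Channel model

The synthesis→PCR→sequencing pipeline is abstracted to: per-oligo
dropout (default 0.7 %), Poisson read coverage per surviving oligo
(default mean 30), and i.i.d. per-base substitutions to a uniformly
random different base (default 0.8 %). The substitution and dropout
defaults are the rates observed in the experiments this package
emulates; coverage 30 is a deliberate desk-scale choice well below the
~112× of the original sequencing runs but far above the consensus
breakdown point. Reads are full-length oligo copies; paired-end overlap
assembly, PCR bias, chimeras and quality scores are not modelled.
Optional insertion/deletion rates exist for robustness experiments
(indel reads are then discarded by the decoder's length filter). Note
that at coverage c, a fraction e^(−c) of surviving oligos draws zero
reads; at coverage 30 this is negligible (~10⁻¹³), but "clean channel"
experiments at low coverage will lose oligos to sampling alone.

## Consensus and classification

A read joins a cluster iff its length is exactly 196, its forward primer
matches a pool within 2 mismatches, its colour tag is within 1 mismatch
of a tag, and its address block is a *valid in-range codeword* — the
operational meaning of "error-free address". Consensus is per-position
majority with ties to the lexicographically smallest base; no alignment
is needed because reads are fixed-length. A designed oligo is
*recovered* when its cluster's consensus parses with all blocks valid at
the expected address, *errored* when a cluster exists but some block is
invalid (its nearest-codeword payload is still passed downstream), and
*missing* otherwise; the three statuses partition the design.

## Restoration

The detector unions decoder provenance (missing/conflict) with a
statistical cross-channel rule: channel X is flagged at a pixel when the
other two channels agree within τ_a = 1 level and each differs from X by
at least τ_d levels. τ_d is adaptive per image: the smallest t ≥ 3 whose
preceding pairwise-difference histogram bin holds ≤ 1 % of mass. The
rule anchors on the point where the *bulk* of the (bimodal) histogram
has emptied rather than on total upper-tail mass — with more than ~1 %
of pixels damaged, a literal upper-tail quantile would move the
threshold past the damage spike it is supposed to catch. When the
histogram never empties (noise-like or heavily saturated imagery) the
statistical detector goes inert and only decoder provenance remains,
which is the correct degradation: the 3-repetition analogy holds only
for channel-correlated content.

Because oligo damage discolours a contiguous Hilbert run while the
per-pixel rule fires on a scattered subset of it, statistical flags are
consolidated along the Hilbert order: gaps of up to 6 unflagged pixels
between flags are closed, and consolidated runs supported by fewer than
r_min = 4 original flags are discarded as isolated false positives.
A genuinely extreme colour (e.g. pure red on a grey background)
legitimately implicates one channel; the run-length requirement plus
decoder provenance is the disambiguation mechanism, and saturated
synthetic art remains the known false-positive regime.

Inpainting is per-channel biharmonic fill of the masked channel-pixels
(scikit-image), exact on constants and within ~2 intensity units on
linear gradients; unmasked pixels are never modified. Smoothing —
bilateral (σ_spatial = 3, σ_range = 30 intensity units, edge-padded)
followed by an adaptive median whose window grows 3→7 until the local
median is not an extreme — is a presentation stage: it blends
quantization blocks but also departs from the quantized reference, so
PSNR comparisons against the quantized original are made on the
inpainting-stage output. PSNR is 10·log₁₀(255²/MSE) with +∞ for
identical images; SSIM is scikit-image's windowed implementation with
the standard stabilizing constants and window size 7 (the
implementation requires an odd window).

Deep-learning inpainting and enhancement used in the original system are
deliberately replaced by these classical counterparts: no trained
weights, same pipeline role, fully reproducible. Absolute PSNR/SSIM
values of the original photographic experiments are therefore not
comparable; the package's claim is the *relative* improvement on damaged
reconstructions, which its tests measure directly.

## LDPC, interleaving, UEP

Codes are column-regular (d_v = 3) Gallager-style draws with row slots
dealt as evenly as possible, a 4-cycle reduction pass, and systematic
form by GF(2) elimination with column pivoting (rank-deficient draws are
redrawn, bounded retries). Decoding is flooding sum-product with exact
zero-handling in the check-node leave-one-out products (erasures enter
as LLR 0), hard-decision early exit, and a 50-iteration cap.

UEP at rate R = 0.75 uses block geometry (k, n) = (726, 968) so each
codeword protects exactly three 242-bit payloads and emits one 242-bit
parity oligo: protecting k oligos costs ⌈k/3⌉ parity oligos — 391 for
1,173 protected, 3.3 % of an 11,826-oligo design. Protected payloads
pass through a seeded uniform interleaver before blocking, so a dropped
oligo's 242-bit erasure burst spreads across codewords. The protected
region is a user-supplied address set; no face detection is attempted.

The mismatched-decoder experiment deserves a note. For a pure binary
symmetric channel far below the code threshold, sum-product decoding is
in practice insensitive to uniform LLR scaling: at n = 1024, R = 0.5,
true p = 0.5 %, decoding succeeds essentially always whether the decoder
assumes 0.5 % or 5 %. The documented experiment therefore operates where
the estimate matters: true p = 5 % (near the practical limit of the
(3,6) code at this length) with the mismatched decoder assuming 45 %.
The overestimate shrinks every channel LLR toward zero and the decoder
no longer converges within its iteration budget — frame success
collapses from ~100 % to ~0 %, a decisive and seed-robust reproduction
of the mismatch penalty. The JPEG+LDPC baseline shows the same effect
end to end: with matched parameters the image survives the channel;
with a grossly mismatched estimate, residual errors break JPEG
decompression (recorded as an outcome, never raised).

## Topological dimension

Only the top strand is modelled: a nick at site occurrence position
p with enzyme offset o cuts at p + o, and offsets are required to be
strictly interior so both the prefix and suffix signatures are
non-empty. Real enzyme catalogues are replaced by a synthetic candidate
generator (random 4–7-nt sites at pairwise sliding-Hamming distance
≥ d_min = 2, where the sliding distance is the minimum Hamming distance
over all end-to-end placements of the shorter site in the longer);
user-supplied tables are accepted as delimited text. Panel selection is
a depth-first search for 7 candidates present in every pool at pairwise
distance ≥ d_min.

Decoding counts adjacent fragment pairs whose junction matches an
enzyme's prefix/suffix; ON iff count ≥ α·(pool maximum), α = 0.2 by
default. The relative threshold needs count statistics: with ~50 site
copies per pool, a spurious nick rate of 1–2 % stays well under α·max
for every α in [0.1, 0.4], whereas in tiny pools (≈ 8 copies) a single
spurious nick can cross α = 0.1. Test pools therefore implant 8 copies
per site for exactness checks (spurious rate 0) and 50–100 oligos per
pool for the thresholded, noisy experiments. An all-OFF pool decodes as
a blank, which also represents the NUL code in exhaustive letter tests.
Sequencing of fragments is abstracted away by default; fragments can
optionally be passed through the read channel with mismatch-tolerant
signature matching.

## Synthetic fixtures

`gradient` (per-channel linear ramps) is the maximally compressible
control; `shapes` adds saturated colour regions (the detector's known
ambiguity case); `noise` is the incompressible control; `photo-like` is
the domain-representative fixture: a shared band-limited luminance field
plus weak per-channel chroma and film-grain-like fine texture, i.e.
channel-correlated, low-saturation imagery of the kind the cross-channel
detector presupposes. Fixtures are deterministic in (kind, size, seed).
Desk-scale experiments use 64×64 images (≈ 300 oligos); at the published
pool scale (≈ 12k oligos) every run would sustain channel damage,
whereas at desk scale a substantial fraction of runs emerges untouched —
restoration comparisons are therefore made on runs that actually
sustained damage. Passing tests on these fixtures demonstrates the
mechanics of the codec, channel, detector and decoder; they do not
certify perceptual quality on photographic material.

## Numerical and degenerate-input choices

Huffman ties break deterministically (weight, then smallest contained
symbol; canonical assignment), so codebooks are reproducible. A
single-symbol alphabet still receives a 1-bit code. Consensus base ties
break to the lexicographically smallest base. BP tanh arguments are
clipped at ±30 and check products at 1−10⁻⁹ before arctanh. Empty reads,
empty pools, fully masked images, zero-count Huffman tables and
oversized words raise explicit `ValueError`s; channel decoding itself
never raises on content errors. All randomness flows through
`numpy.random.default_rng` seeds carried in configs and signatures;
integer bit fields are MSB-first, and on-disk bit containers pack
little-endian.

## Known limitations

- Whole-image decode quality at photographic scale is not validated
  (desk-scale fixtures only; no deep enhancement stage).
- The channel has no PCR bias, position-dependent error profile or
  quality modelling; indels are off by default.
- The statistical detector is inert on channel-uncorrelated content by
  construction.
- LDPC degree profiles are fixed regular (d_v = 3); no optimized or
  irregular designs.
- The duplex geometry of nicking (bottom strand, two-subpool readout
  chemistry) is outside the single-strand abstraction.
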