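# twodna — two-dimensional DNA data storage, simulated end to end

`twodna` implements and tests a storage architecture that records
information in **two dimensions of a DNA oligo pool**: images in the
*sequence* of synthetic 196-nt oligos, and rewritable metadata in the
*topology* of the backbone, as nicks written by mixtures of nicking
endonucleases. It is aimed at researchers in molecular information
storage and coding theory who want a faithful, fully simulated sandbox
for this architecture — every wet-lab step (synthesis, PCR, MiSeq
sequencing, enzymatic nicking, ligation) is replaced by an explicit
channel or process model, so the whole write–read–erase–rewrite cycle
runs on a laptop.

## The method

**Sequence dimension (images, redundancy-free).** An RGB image is split
into its R, G, B channels; each channel is quantized from 256 to 8
intensity levels (3 bits). Pixels are linearized along a Hilbert
space-filling curve, which preserves 2-D locality, and partitioned into
eight subsets by quantized level. Within a level, pixel positions are
differentially encoded (gaps Δᵢ = pᵢ − pᵢ₋₁ along the curve) and Huffman
coded, exploiting the bias toward small gaps in smooth imagery. The
coded stream is chopped into independently decodable 242-bit segments,
each opening with an absolute position anchor, so that one lost oligo
discolours only one contiguous pixel run. Binary data maps to DNA via
enumerative (rank/unrank) coding over a constrained language — 22 bits →
13 nt for payload, 16 bits → 10 nt for addresses — with per-block GC
windows, G-runs ≤ 3 and no `GG` at block edges, so every assembled oligo

```
[20 nt primer][3 nt colour tag][10 nt address][11 × 13 nt payload][20 nt primer]  = 196 nt
```

satisfies GC ∈ [40 %, 60 %] and max G-run ≤ 3 end to end. **No
error-correction redundancy is added.** After the channel
(substitutions, oligo dropout, Poisson coverage), reads are binned by
valid address, reduced to per-position majority consensus, and decoded.
Damage shows up as block discolorations in a single colour channel; the
three-channel decomposition acts as a natural 3-repetition code, so a
detector flags the one channel that disagrees with the two concordant
others (adaptive thresholds read off the pairwise level-difference
histograms, flags consolidated along Hilbert-order runs), and the
flagged pixels are re-filled by biharmonic inpainting, optionally
followed by bilateral + adaptive-median smoothing.

**Optional unequal error protection.** For high-value regions, a
systematic regular LDPC code (rate 0.75) protects only the designated
oligos: each codeword covers three 242-bit payloads and emits one parity
oligo, behind a seeded interleaver that decorrelates dropout bursts.
A JPEG+LDPC joint source–channel baseline with a *mismatched* decoder
(belief propagation initialized with a wrong channel error estimate) is
included for comparison.

**Topological dimension (metadata, rewritable).** Seven nicking
endonucleases map to the seven bits of ASCII; a letter is written into a
pool by adding exactly the enzymes whose bit is 1 (ON/OFF encoding, one
letter per intensity pool). Nicking fragments the top strand; decoding
counts, per enzyme, fragment boundaries flanked by the enzyme's site
prefix/suffix and thresholds counts at a fraction α of the pool maximum.
T4-ligase sealing erases the word; rewriting is ligation followed by a
fresh round of nicking.

## Worked example

```python
import twodna
from twodna import pipeline as pl, dna_codec as dc
from twodna.fixtures import generate_fixture

primers = dc.design_primers(seed=12345)
img = generate_fixture("photo-like", (64, 64), seed=0)
cfg = pl.PipelineConfig(seed=0, do_smooth=False)   # 0.8% subs, 0.7% dropout, coverage 30
report, decoded, restored, enc = pl.run_pipeline(img, cfg, primers)
```

prints (via the fields of `report`):

```
designed oligos      : 296 (224 data + 72 header)
recovered/errored/missing: 245/0/3
coded bits           : 60016  (ratio 1.63 of 3-bit raw)
PSNR decoded vs quantized original : 31.12 dB
PSNR restored vs quantized original: 43.36 dB
masked channel-pixels: 58
```

Three oligos never made it through the simulated pool (dropout), which
discolours three pixel runs in single channels; the cross-channel
detector masks 58 channel-pixels and inpainting lifts the reconstruction
from 31.1 dB to 43.4 dB against the quantized original. The same flow is
available from the shell:

```bash
twodna fixture --kind photo-like --size 64 --seed 0 -o img.png
twodna encode --image img.png -o design.fa
twodna simulate --fasta design.fa --p-sub 0.008 --p-drop 0.007 --coverage 30 --seed 7 -o reads.fq
twodna report --raw-bits 8654400 --nts 2317896
#  -> raw density 3.73 bits/nt; quantized density 1.40 bits/nt; structural overhead 27%
twodna nick-write --word ILLINOIS --seed 4 -o frags.fa
twodna nick-read --fragments frags.fa --seed 4      # -> ILLINOIS
```

## Layout

| module | role |
| --- | --- |
| `twodna.image_codec` | quantization, Hilbert order, gap+Huffman level streams |
| `twodna.dna_codec` | constrained block codes, oligo assembly/parsing, primers |
| `twodna.channel_sim` | substitution/dropout/coverage channel, FASTA/FASTQ I/O |
| `twodna.consensus` | address binning, majority consensus, recovery report |
| `twodna.restoration` | discoloration detection, inpainting, smoothing, PSNR/SSIM |
| `twodna.uep_ldpc` | LDPC + BP, interleaver, unequal error protection, JSCC baseline |
| `twodna.topo_codec` | enzyme panels, nick writing, fragment decoding, erase/rewrite |
| `twodna.fixtures` / `twodna.pipeline` / `twodna.cli` | synthetic images, orchestration, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
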