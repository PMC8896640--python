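# Methods

This note documents the models and stream formats implemented in
`cramcodecs`, the parameter choices that matter, what the synthetic data
generators do and do not emulate, and the package's known limitations.
The byte-level formats described here are this package's own dialect:
they are self-describing and stable, but byte-stream compatibility with
other implementations of the same codec families is not claimed.

## Shared stream conventions

All containers begin with one flag byte: bit 0 = model order (0/1),
bit 1 reserved (must be zero), bit 2 = 32-state interleave, bit 3 =
STRIPE, bit 4 = size omitted, bit 5 = raw storage ("cat"), bit 6 = RLE,
bit 7 = PACK.  Lengths and counts are stored as varints ("uint7"): seven
data bits per byte, most-significant group first, 0x80 continuation bit,
minimal length (1–5 bytes for values below 2^32).  The most-significant-
first layout was chosen so encoded integers sort lexicographically; any
self-consistent choice would round-trip.

## rANS Nx16

The entropy coder keeps `N ∈ {4, 32}` independent 32-bit accumulators in
the interval `[2^15, 2^31)`, renormalizing by emitting 16 bits whenever
an encode step would overflow.  Input byte `i` is handled by lane
`i mod N`; because rANS is last-in-first-out the encoder walks the input
backwards and the renormalization words are written in reverse, so the
decoder reads them forward.  Final states are flushed as `N` little-endian
32-bit words ahead of the word stream.

Symbol probabilities are static per block.  Order-0 frequencies are
normalized to 12 bits of precision by largest-remainder apportionment
(ties broken by ascending symbol value; every observed symbol keeps a
frequency ≥ 1, with the borrowed mass taken back from the most frequent
symbols).  Order-1 keeps one table row per observed context, where the
context of byte `i` is byte `i−1` and each lane's first byte uses
context 0.

Two refinements keep Order-1 headers small enough that the Order-1 +
PACK combination is useful at block scale:

* **Per-row precision.**  Each row is normalized to
  `min(10, max(ceil(log2 n_present), bit_length(count) − 2))` bits.
  Heavily-used contexts keep the full 10 bits; rarely-visited contexts
  get coarse, cheap-to-store frequencies.  Since the decoder knows the
  context before reading a slot, per-row precision costs one byte per
  row and nothing at decode time.
* **Table self-compression.**  The serialized Order-1 table (run-encoded
  symbol lists plus uint7 frequencies per row) is itself passed through
  the Order-0 coder and stored compressed when smaller.  With PACK the
  literal alphabet approaches 256 and an uncompressed flat-precision
  table costs 6–8 KB per block — more than the Order-1 modeling gain at
  1 MB blocks.

Transforms compose as STRIPE → PACK → RLE → entropy coding, and the
decoder applies the inverse chain.  A striped container stores the
stream count, each sub-container's byte length, then recursively framed
sub-containers.  PACK metadata is the symbol table (codes are assigned
in ascending symbol order, packed LSB-first within each payload byte;
one symbol uses zero bits).  RLE stores the run-symbol set, then the
run-length stream as a nested Order-0 container — lengths use
255-continuation chunking (a 255 byte means "add 255 and keep reading")
so unbounded runs round-trip — then the entropy-coded literal stream.

RLE's run-symbol set is chosen by exact per-symbol accounting: a symbol
is included iff the literal bytes its runs save exceed the bytes its
length entries cost.  Because including one symbol never changes another
symbol's accounting, this equals the subset-exhaustive optimum (the test
suite checks this against brute force on small alphabets).

## Adaptive arithmetic coder

The range coder is the classic carry-propagating construction: 64-bit
low, 32-bit range, byte-wise renormalization below 2^24, five flush
bytes.  The decoder reads bytes past the payload end as zero, and the
payload is length-prefixed, so streams are self-delimiting.

Adaptive models hold one count per symbol, initialized to 1.  A coded
symbol's count grows by 16; when the total reaches 2^13 all counts are
halved (floored at 1).  The increment/rescale pair bounds the coder's
precision loss (total ≤ 2^13 keeps `range/total` large) while keeping
the model responsive to non-stationary data; any fixed rule would
round-trip, this one is the documented choice.  Order-1 conditions each
symbol's model on the previous literal (initially 0).  In RLE mode each
maximal run is coded as one literal plus its extra length in 0–255
chunks (255 = continue) through an adaptive model indexed by the run's
symbol, so run statistics are learned per symbol.  Models above Order-1
are deliberately not provided.

## FQZComp quality codec

Quality values (up to 94 distinct symbols, covering both Phred 0–63 and
the 0–93 PacBio range) are coded with the adaptive range coder under a
16-bit context assembled from four bit-fields:

```
context = (qctx mod 2^qbits) << qloc        # recent qualities
        | ptab[min(pos, 1023)]  << ploc     # position along the read
        | dtab[min(delta, 255)] << dloc     # cumulative difference count
        | selector              << sloc     # verbatim per-record bits
```

after coding symbol `q`, `qctx ← (qctx << qshift) + qtab[q]` (masked to
16 bits); `delta` increments whenever a quality differs from its
predecessor.  The fields must not overlap and their widths sum to ≤ 16.
Position clamps at 1023 and delta at 255 before table lookup.  One
adaptive model exists per context value, created lazily.

The parameter block — version, flags, alphabet map, field widths and
positions, and each enabled lookup table run-length encoded — is written
at the head of the stream, so any parameter choice decodes with the same
decoder.  Per-record metadata holds lengths (one value when all records
share a length), reverse and duplicate flag bitmaps, and bit-packed
selectors.  A duplicate record (same qualities as its predecessor)
contributes only its flag; a reversed record is coded right-to-left and
restored on decode.

### Presets

`build_params` derives the alphabet map from a sample and fills one of
four context layouts.  The guiding constraint is **block-scale
trainability**: adaptive models start flat, so a context space must be
small enough that its models converge within one block (10^5–10^6
symbols), or the learning cost exceeds the modeling gain.

| preset | qbits/qshift | pbits | dbits | sbits | intent |
|---|---|---|---|---|---|
| `generic` | 12 / ≤6 | 2 | 2 | 0 | deep history, any alphabet |
| `small_alphabet` | 6 / 2 | 4 | 3 | 0 | 4-value data: 3 recent values, 2 bits each |
| `position_heavy` | 7 / ≤7 | 7 | 2 | 0 | exact cycle tracking over 128 cycles |
| `selector_read12` | 3 / ≤3 | 3 | 1 | 1 | read-1/read-2 splitting |

`selector_read12` is deliberately lean: splitting every context in two
by the selector halves each model's training data, which only pays when
both halves still converge — and the selector only carries information
about population differences that quality history cannot reveal (e.g.
cycle-specific errors confined to read 2).  When the populations differ
in ways history already exposes, the selector is near-neutral and costs
at most its one bit per record of metadata; the test suite asserts the
strict improvement on a paired corpus with read-2-specific cycle errors
and the metadata-cost bound on a corpus without them.

The sequence-base context is intentionally excluded: conditioning
qualities on the called bases would couple two otherwise independent
data streams.

## Read-name tokenizer

`split_raw` fragments a name into maximal digit runs (chunked to ≤ 10
digits, a 10-digit chunk ≥ 2^32 split 5+5, so numeric values fit 32
bits), maximal ASCII letter runs, and single characters.  Each fragment
at column `t` is compared with the previous name's fragment at the same
column: byte-identical → MATCH; both numeric with no leading zeros and
a difference in [0, 255] → DDELTA; both numeric with the same leading-
zero count and total width and a difference in [0, 255] → DDELTA0;
otherwise a literal CHAR/ALPHA/DIGITS/DIGITS0 token.  Negative
differences always fall back to literals.  A name with fewer columns
than its predecessor is padded with NOP tokens (empty expansion) so
column counts stay aligned when different naming styles interleave;
END terminates every token list.  Comparison is against the immediately
preceding name only — simpler than searching several candidates, still
lossless.

Serialization: a name count, then per column a type stream (one byte
per name still active in that column) followed by one value stream per
token type present (CHAR: byte; ALPHA: length-prefixed; DIGITS: 32-bit
little-endian, the width implied by the value; DIGITS0: width byte plus
value; deltas: one byte).  The decoder reconstructs the column layout
from the type streams alone — the number of names reaching column
`t+1` is the number of non-END entries in column `t` — so no extra
geometry is stored.  Each stream is compressed independently: "fast"
level tries raw storage and Order-0 rANS; "max" additionally tries
Order-1, PACK+RLE and the adaptive coder, keeping the smallest.

## Synthetic data

The generators produce the study conditions for every test; all are
deterministic in their seed (numpy `default_rng`).

**NovaSeq-like** qualities are the binned output of a latent per-read
quality level following a Gaussian random walk (volatility 0.4 for good
clusters, 1.6 for the 25% low-quality sub-population; slight downward
drift; levels clipped to [0, 30] and thresholded at 3/8/20 into Phred
2/12/23/37).  This latent-level mechanism — rather than a first-order
Markov chain over the four symbols — is what gives the data the two
properties real binned quality strings have and that the codec
comparisons depend on: very long top-bin runs whose lengths are far
from geometric (good reads sit deep inside the q37 bin and often span
whole reads), and bursty boundary-hover stretches whose statistics
depend on more than one previous symbol.  On a first-order chain a
static Order-1 coder is optimal by construction and neither the
context-model codec nor the RLE/PACK transforms could show their
documented advantages.  The default corpus is 10000 reads × 100 cycles
(~1 MB of quality values), the block size at which the block codecs are
normally compared; at a tenth of that the static Order-1 table overhead
genuinely reverses the PACK+RLE comparison.

**HiSeq-2000-like** qualities use a 40-state smooth random-walk Markov
chain plus cycle-specific miscalls (a ramp toward late cycles and two
deliberately bad cycles); miscalls replace the emitted value only, so
the underlying cluster quality recovers immediately.  In paired mode,
read-2 records suffer dense scattered erroneous cycles while read 1
stays nearly clean — the regime where the read-1/read-2 selector bit
carries information that no quality history can provide.

**PacBio-CLR-like** qualities are i.i.d. draws from a broad marginal
over 0–93 (lag-1 autocorrelation ≈ 0), reproducing the near-
incompressibility of that platform's quality values.

**Read names** follow `instrument:run:flowcell:lane:tile:x:y` with
fixed-decimal-width coordinates (tile 4, x 5, y 6 digits) advancing
monotonically, so name-sorted output is also lexicographically sorted
and consecutive names differ in at most two numeric fields.
Position-scrambled order is a seeded uniform permutation of the sorted
list, standing in for coordinate-sorted alignments without needing any
alignment machinery.

What passing tests on this data do *not* show: real instrument data has
instrument- and library-specific artifacts (tile effects, adapter
read-through, duplicate structure, quality recalibration signatures)
that no small parametric generator reproduces, so the compression
ratios measured here indicate ordering and rough magnitude, not the
exact ratios any particular dataset will achieve.

## Numerical and degenerate-input choices

* Empty inputs: every container stores length 0 and nothing else;
  Order-1 entropy coding of an empty public input is rejected (there is
  no context structure to build), but containers handle empty data
  uniformly.
* `normalize_frequencies` is exact integer arithmetic; no floating
  point enters any coded stream, so outputs are platform-independent.
* The range coder's decoder treats bytes past the payload end as zero —
  the encoder's flush may legitimately omit trailing 0xFF-carry bytes.
* Run lengths, positions and deltas clamp rather than overflow.
* Malformed streams raise typed exceptions (`TruncationError`,
  `MalformedError`, `UnsupportedFormatError`) rather than producing
  wrong data; decoders validate table sums, stream lengths and flag
  bits.

## Problem sizes

The test suite and benchmarks run at desk scale: ~1 MB quality blocks
(10000 × 100), 10^5-symbol entropy-convergence checks, 5000-name
corpora, and randomized property sweeps with inputs up to a few KB.
These sizes were chosen so that static-table overheads, adaptive-model
learning costs and modeling gains sit in the same proportions as at the
codecs' normal operating block sizes.

## Known limitations

* Single scalar implementation; no SIMD or threading.  Throughput is
  that of pure Python — suitable for study and verification, not for
  production-scale compression.
* Stream formats are this package's dialect; cross-implementation byte
  compatibility is future work.
* FQZComp presets are fixed layouts, not learned per dataset; model
  auto-tuning is out of scope.
* Lossy quality transforms are out of scope by design.
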