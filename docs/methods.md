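# Methods

`seqzip` is a lossless, reference-free compressor for DNA sequence data
and a compression-based analysis tool. This note documents the models it
implements, the parameters that matter, the numerical choices that make
encoder and decoder bit-exact, what the synthetic corpora do and do not
emulate, and the known limitations.

## Channel model

A FASTA/FASTQ file is split into independent channels: sequence symbols
(2-bit alphabet {A,C,G,T}), headers, FASTQ `+`-line text, qualities, an
exception side-channel, a lowercase (soft-masking) case mask, and line
layout metadata. Only the sequence channel is modelled by the ensemble
below; the side channels go through small adaptive order-k byte models
(order 3 for headers, 2 for qualities, 1 for the structural channels)
over a 256-symbol alphabet, with the same arithmetic coder. Out-of-
alphabet characters (N, IUPAC codes) are replaced in the symbol stream by
index 0 and recorded as (position, character) exceptions, which keeps the
2-bit model space pure while guaranteeing byte-exact reconstruction.
Soft-masked bases are uppercased for modelling; a run-length mask
restores case. Only `\n` line endings are accepted (a `\r` fails fast),
and FASTQ must be the standard four-line form: the reconstruction
contract is byte-for-byte identity, so ambiguous layouts are rejected
rather than normalized.

## Sequence models

**Finite-context models (FCM).** An order-k FCM predicts
`P(s|ctx) = (n_s + α) / (Σ n + |Σ|α)` from per-context counters. α
defaults to 1 for k < 10 and 1/16 for deeper orders, where contexts are
sparse and sharper estimates pay off; both are standard in the FCM
compression literature. Counters are 8-bit; when one reaches 255 the
whole context row is floor-halved, which bounds memory and makes the
model track recent statistics. When `4^k` exceeds the table budget
(default 2^24 rows) contexts are mapped by a fixed multiplicative hash
(64-bit golden-ratio constant, power-of-two table); collisions share
counts silently and deterministically. With `inverted_repeats` enabled
the model also counts each event's reverse-complement image, so both
strands feed the same table — a well-known genomic feature worth
modelling at the deeper orders of the maximal presets.

**Substitution-tolerant context models (STCM).** An STCM shares the
count table of a same-order FCM but maintains its own context: on a
mismatch between the true symbol and the model's most probable symbol,
the *predicted* symbol is propagated into the context and a substitution
counter increments; a match decays the counter (floor 0); exceeding the
allowance `t` resets the context to the true history. The STCM never
writes to the shared table — its paired FCM performs the counting — which
bounds memory and avoids double-counting. This is what lets a deep
context survive the isolated substitutions that separate diverged
repeats; on a template plus a 1%-mutated copy, the order-12 STCM codes
the mutated half in fewer bits than the plain order-12 FCM (asserted in
the test suite).

**Repeat (copy) models.** A repeat model keeps a pointer into the
already-seen sequence and bets the next symbol equals the pointed one,
with `P(hit) = (Nh+1)/(Nh+Nm+2)` and the complement spread uniformly over
the other three symbols. Both quantities are precomputed in two lookup
tables for all `Nh+Nm ≤ 200` (models rarely survive longer) and computed
analytically — by the identical expression, hence bit-identically —
beyond. Model health is the low-pass filtered miss indicator
`Y ← X + βY` with X = 1 on miss and 0 on hit; the model stops when
`Y > L`. Defaults β = 0.9, L = 7, under which a fresh model dies after
exactly 12 consecutive misses. Candidate start positions come from a
cache table holding the `c` most recent positions of each k-mer (exact
2k-bit keys, stored sparsely; worst case `4^k·c` entries; k > 15 is
rejected since the exact-key store becomes prohibitive), and the
candidate is chosen by a Numerical-Recipes LCG (multiplier 1664525,
increment 1013904223, modulus 2^32) with a seed stored in the container,
so the decoder replays the same choices. The scheduler runs at most
`n_models` models per bank, attempts at most one start per bank per
step, queries the cache *before* inserting the current position (a model
may never point at the symbol it is predicting), and frees a stopped
model's slot immediately.

## Mixing

The coding distribution is the convex blend `Σ w_m P_m(s)`. After each
symbol, `w_m ← w_m^γ · P_m(observed)`, floored at 1e-6 and renormalized.
γ = 1 gives exact Bayesian mixture updating; the default γ = 0.95
forgets the distant past so the mixture switches within tens of symbols
when a repeat model starts performing — the behaviour repeat-rich
sequences demand. The floor prevents permanent lock-out; after
renormalization a weight can sit marginally below the floor (flooring
and summing to exactly 1 are jointly unsatisfiable), which is harmless
and covered by tests as "never underflows to zero". Every profile
carries one static uniform slot, and an idle repeat-model slot also
contributes the uniform distribution: the blend is therefore always
defined (even before any repeat model starts) and the scheme stays
deterministic without re-initializing weights on model starts. The
mixer is an interface with this one shipped implementation; a different
mixer (e.g. a learned one) can be swapped in without touching the coder.

## Entropy coding and container

The coder is a classic CACM-style arithmetic coder: 32-bit low/high
registers, pending-bit underflow handling, bit-level output. Blended
probabilities are quantized to integer frequencies summing to 2^16 with
every symbol ≥ 1 (largest-remainder apportionment, ties to the lower
index), identically on both sides — the only way floating-point blends
can drive integer range coding bit-exactly across platforms. The
blend additionally floors every symbol at 2^-16 before quantization so
no codable symbol ever has zero probability. Measured payloads sit
within a few bytes of `Σ −log2 p` (the test suite asserts 0.1% + 64
bytes), and the bit-information profile uses the same quantized
probabilities, so profile totals reconcile with payload sizes to within
the coder's constant flush cost.

The container is little-endian and length-prefixed: magic `SQZ3`,
version, the fully resolved profile as JSON (every model parameter and
the LCG seed — decompression never consults the preset table), original
length, CRC-32 of the original bytes, then named channel blocks. The
CRC is verified after reconstruction; bad magic/version and corrupt
payloads raise distinct error types (exit codes 2 and 3 in the CLI).

## Presets

Nine presets in three groups (three each). *Efficient* (levels 1–3):
repeat models only — level 1 is the single k=13, c=8 model. *Optimized*
(4–6): FCM banks (e.g. k ∈ {3,8,13} at level 5) plus repeat models and
an STCM (t=3). *Maximal* (7–9): six to seven FCMs up to k=14,
inverted-repeat counting, four repeat-model slots, two STCMs. Each
profile's memory ceiling (count-table rows, worst-case cache entries,
lookup tables) is computed a priori from its configs and checked before
any allocation.

## Synthetic corpora

The generator produces, deterministically from a spec and seed: uniform
i.i.d. DNA (entropy exactly 2 bits/base), order-m Markov chains with
Dirichlet-sampled transition rows (analytic entropy rate from the
stationary distribution, found by power iteration), tandem arrays (one
unit tiled, substitutions applied to every copy after the first),
dispersed repeats, and mutated copies — each with ground-truth metadata
(entropy rates, repeat coordinates, substitution positions). Sequence
and mutation randomness use split substreams, so changing the
substitution rate never changes the underlying sequence. Study
conditions fixed across the tests: i.i.d. and Markov corpora of 10^6
symbols; the repeat corpus is a 1 kb unit × 200 copies at 0.1%
substitutions. These corpora have known, stationary structure; real
genomes mix regimes, carry long-range composition changes, inverted and
diverged repeats, and assembly artifacts. Passing tests therefore
demonstrate correctness and calibration of the machinery, not the
compression ratios achievable on any particular genome.

## Numerical and design choices

- Quantization ties break toward the lower symbol index; `argmax` over
  counts breaks ties the same way. Both choices are arbitrary but must
  be fixed: encoder/decoder symmetry is exact, not approximate.
- The hash used for over-budget context tables degenerates to the
  identity when the exact table fits, so direct and hashed storage are
  interchangeable in that regime.
- An empty file is a valid input (empty container, empty output);
  an empty sequence is rejected only where a quantity (NC) divides by n.
- The repeat-model stop filter treats X as the *miss* indicator, so Y
  accumulates recent failure and crossing L stops the model; hits decay
  Y multiplicatively and cost nothing.
- Side channels are coded independently with fresh byte models; their
  payloads dominate only for header/quality-heavy FASTQ, which is not
  the use case the sequence ensemble targets.

## Limitations

- Pure-Python inner loop: throughput is tens of kilobases per second per
  model bank — suitable for analysis-scale inputs, not for multi-gigabyte
  archival runs.
- No neural mixing; the soft-blending weights are the only shipped mixer.
- No random access into containers, no multi-threading, no hash-table
  repeat models for k > 15, no protein alphabets, no SAM/BAM/CRAM.
- FASTQ is restricted to four-line records; multi-line FASTQ is rejected
  rather than guessed at.
- Normalized Compression uses sequence-channel payload bits only
  (headers, qualities and framing excluded): NC is a property of the
  symbolic sequence, and framing would add noise to comparisons.
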