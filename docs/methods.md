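# Methods

## Canonical alignment

The engine's central trick is to replace pairwise alignment at search time
with a one-off projection of every sequence onto a fixed catalogue of
alignment slots. A slot is an IMGT position plus an insertion ordinal
(A → 1, B → 2, …; 0 = no insertion). The default catalogue has 200 slots:
the 128 plain IMGT positions and 36 insertion slots each at positions 111
and 112, which is where the IMGT convention places CDR3 insertions. Slot
order follows the IMGT traversal rule — plain positions ascending,
insertions at 111 ascending, insertions at 112 *descending* into plain 112
— so physically adjacent residues of a long CDR3 loop occupy adjacent
slots. Insertion codes are stored as ordinals rather than letters so this
ordering is purely numeric and lives in exactly one place.

The catalogue is fully loadable from a tab-separated definition file, and
its content hash (`scheme_id`, SHA-256 of the ordered slot list plus the
alphabet) is stamped into every database manifest. Searching a database
with a query encoded under a different scheme is a hard error, never a
silent misalignment. The residue alphabet is the 20 standard amino acids
plus `X`, coded 1–21 with 0 reserved for gaps.

A sequence whose numbering contains a key outside the catalogue (a rare
insertion — e.g. a spurious 8-residue insertion at position 81, or very
long camelid CDR3s) cannot be vectorised. `encode` returns it as an
`UnusualSequence` marker carrying the offending keys; the database builder
writes these to a FASTA sidecar. Every input is thereby classified into
exactly one of {encoded, unusual, error}, and the builder enforces
`encoded + unusual + filtered = inputs` on every build.

## Identity definition

Over a region mask (a set of slots), with optional terminal trimming
applied first:

* **matches** — slots where both codes are equal and non-gap, and (by
  default) not the ambiguous code `X`;
* **denominator** — slots where at least one code is non-gap, i.e. an
  indel present in only one sequence counts as a mismatch; slots empty in
  both are ignored;
* **identity** = 100 · matches / denominator, defined as 0 when the
  denominator is 0.

The denominator choice (union of residue-bearing slots) is the one place
the definition is genuinely open: an alternative reading uses the larger
of the two region lengths. The two coincide except when both sequences
have interior one-sided gaps at *different* slots inside the region; the
union rule is implemented in one function each in the engine and the
oracle, so swapping it is a two-line change.

Variants:

* **Length-matched mode** compares a pair only when both sequences carry
  the same number of residues (non-gap codes) inside the mask. Counting
  residues rather than slot spans makes the rule insertion-aware. The
  default region suite applies it to the CDR and CDR3 masks, not to the
  whole domain.
* **Terminal trimming** (off by default) removes masked slots before the
  later of the two sequences' first residues and after the earlier of
  their last residues, so truncated reads are not penalised for missing
  ends.
* **Ambiguity**: `X` matches nothing, including another `X`, so ambiguous
  reads can never inflate identity; a flag restores literal matching.

Matches and denominators are exact integers; the division to a percentage
is performed once, in float64, at reporting time. Distinct fractions with
denominators ≤ 200 are ≥ 1/40 000 apart, far above float64 resolution, so
equal percentages are exactly equal and the ordering is reproducible —
ties are genuine ties, broken by ascending database row.

Thresholds (e.g. "hits at 90% or better") are applied inclusively (≥);
hits failing the threshold never occupy accumulator capacity, so a
threshold combined with `n_best` returns the n best hits *at or above* the
threshold.

## Search

The scan is exhaustive: every row of every selected shard is scored for
every query and region; no prefiltering of any kind exists in the code
path. Shards stream through memory in manifest order; each loaded chunk is
scored against all queries and all regions before the next chunk is read
(batching queries amortises the I/O-bound loading step, which dominates at
scale). Per-(query, region) accumulators hold at most `n_best` entries and
are merged in chunk order with the same tie rule, which makes the output
provably independent of `chunk_rows` and of the worker count — workers
parallelise chunk scoring, but merging is deterministic in submission
order. Partition selection defaults to all partitions matching each
query's chain type.

## Database layout

Shards are raw uint8 binary matrices (dimensions in the manifest) plus a
parallel int64 file of `(metadata_file_id, row_in_file)` pairs — memory-
mappable and language-neutral. The manifest is a plain-text key/value
header plus a shard table with SHA-256 content hashes, checkable without a
database engine; metadata stays in the original CSV files, addressed by
the index pairs, so nothing is copied. Default shard size is 2²⁰ rows,
bounding per-chunk memory while keeping per-shard overhead low.

The reduction filters used to derive smaller database variants run in a
fixed order — ambiguous residues, redundancy below threshold (default 5
when enabled), missing residue at position one, exact duplicates — and
each dropped record is counted against exactly one rule. Redundancy comes
from the metadata column when present and falls back to exact-duplicate
counting within the build input, since upstream redundancy annotations are
not otherwise reproducible.

## Paratope extraction

A paratope residue is any antibody residue with at least one heavy
(non-hydrogen) atom within a cutoff (default 4.5 Å, the conventional
contact distance) of any antigen heavy atom. All heavy atoms are used by
default — the most inclusive reading of "residue within 4.5 Å" — with a
side-chain-only option. The chain sequence is numbered by the configured
backend and mapped onto the structure residues by locating the numbered
subsequence within the chain; flanking residues that fail to map
(expression tags, constant domain) are ignored with a warning. Output is
monotone in the cutoff by construction.

## Numbering backends

Numbering itself (an HMM alignment problem) is out of scope. The package
defines the contract plus two backends: a fixture backend that looks
sequences up in a tabular numbering file (used by every test, so the
repository needs no external tool), and a documented subprocess adapter
for an ANARCI-compatible command-line numberer that fails loudly at
construction when the tool is absent — never a silent fallback.

## Synthetic repertoires

The generator emulates what matters to the search problem: a fixed
framework template per chain type (heavy and kappa-like light) with point
mutations at a per-position rate (default 0.03, in the range of typical
somatic hypermutation loads); CDR3s of uniformly drawn length (default
8–20 residues, within the common human heavy-chain range) mapped onto the
105–117 + insertion slots by the IMGT junction rule; optional per-residue
ambiguity (default 0); species/disease/V-gene/J-gene labels and a
geometric redundancy count (p = 0.5) for the metadata table. Mutated and
CDR3 residues are drawn from fixed per-position Dirichlet frequency
profiles rather than uniformly, so identity distributions resemble real
repertoires — high framework identity, diverse CDRs — which is the regime
that actually exercises tie handling.

Two routes share one sampling implementation: a vectorised matrix
generator (fast, used for the large randomized trials) and an object
route that decodes the matrix into numbered sequences (used to exercise
the full numbering → encoding → build pipeline). The two are exactly
consistent by construction.

What the generator does **not** emulate: real V(D)J recombination and
germline gene usage, insertion/deletion variation inside the framework,
sequencing-error profiles, and clonal lineage structure. Passing tests
therefore demonstrate correctness of the alignment, identity and search
machinery on realistically *shaped* data, not biological fidelity of the
sequences themselves.

`plant_neighbors` produces variants at an exact substitution distance
within a mask, giving closed-form expected identities
(100·(m−e)/m for e edits among m masked residues), and
`make_toy_complex` builds a PDB-format complex whose contact set is known
by construction (contact residues at 3 Å, the rest at 20 Å).

## The oracle

`absearch.oracle` is a scalar, pair-at-a-time reimplementation of the
identity definition and of ranked search: a naive double loop over all
pairs with a full sort. It shares no code with the numpy kernels — its
independence is what makes equivalence meaningful. The randomized
equivalence trials (100 trials, database sizes drawn log-uniformly from
10³–10⁴ to span that range at tractable oracle cost, one query per trial,
whole-domain and CDR3 masks) require the engine's rank-1 hit and full
ordered top-100 list to equal the oracle's exactly, on every trial.

## Numerical and degenerate-input choices

* Gap code 0 makes "either non-gap" and "both non-gap" single comparisons.
* Empty denominator (no residues in the mask on either side) → identity 0,
  comparable.
* An all-gap vector has an empty terminal span; trimming against it
  empties the effective mask.
* Ties in `top_n` break by ascending row id; merging accumulators
  re-applies the rule, so streamed and whole-database results are
  identical.
* `resolve_metadata` is injective per database: distinct rows never share
  an index pair (verified by build-time bookkeeping tests).

## Known limitations

* Only V domains are modelled; constant domains are out of scope.
* The exact published 200-position catalogue is approximated by the
  IMGT-convention default (1–128 + 36×2 CDR3 insertion slots); any other
  catalogue can be loaded from a file and is honoured end-to-end via the
  scheme hash.
* Substitution-matrix similarity (BLOSUM-style scoring of more distant
  matches) is deliberately absent from the search path.
* Worker parallelism uses threads; at desk scale the numpy kernels release
  the GIL only partially, so workers > 1 buys determinism-preserving
  concurrency, not linear speedup.
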