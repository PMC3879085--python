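# Methods

## Data model

A PDB entry is held as `Structure → Model → Chain → Residue → Atom`, each
level an ordered container preserving document (file) order. The field set
per level follows the PDB v3.3 `ATOM` record definition: serial, name,
altLoc, resName, chainID, resSeq, iCode, x/y/z, occupancy, tempFactor,
segID, element, charge. Design choices at this layer:

- **Alternate locations and "mutant" residues are record-stream facts.** An
  atom observed at several positions appears as several `Atom` entries in
  the same residue, differing in `alt_loc`; no occupancy-based filtering
  happens at parse time. Duplicate (name, altLoc) pairs are reported by
  `lint()`, not rejected — real archive files contain them.
- **HETATM is a boolean on the atom**, not a separate type: it changes only
  the record name on output. Waters and ligands stay in whatever chain the
  file puts them (including the blank chain id).
- **Atom names are stored stripped.** The writer regenerates column
  justification (single-letter elements start at column 14, two-letter
  elements at column 13, 4-character names fill 13–16), so normalization is
  a by-product of any write.
- **Metadata is verbatim.** Non-coordinate records are kept byte-identical,
  tagged head/tail relative to the coordinate block. Their contents
  (SEQRES, HELIX, CONECT, …) are deliberately not interpreted. Input is
  treated as single-byte text (latin-1 decoding), so stray non-ASCII bytes
  in comments survive a round trip.
- Occupancy is not constrained to [0, 1]; only coordinate finiteness and
  non-negative serials are hard invariants.

## Codec

Fields are sliced at fixed 1-based columns (record name 1–6, serial 7–11,
name 13–16, altLoc 17, resName 18–20, chainID 22, resSeq 23–26, iCode 27,
x/y/z 31–54 in 8.3 format, occupancy 55–60, B 61–66, segID 73–76, element
77–78, charge 79–80). Decoding is total: any failure returns a `ParseError`
rather than raising, which is what lets a whole-archive run complete with
errors collected instead of crashing.

Two strictness levels exist because the archive itself is not uniformly
strict: **lenient** (the reading default) accepts lines truncated after the
coordinates and substitutes occupancy 1.00, B 0.00 and empty trailing
fields; **strict** (the validation/normalization path) requires ≥ 66
columns with all numerics present. Charge is kept as its raw 2-character
string (e.g. `2+`) — interpreting it buys nothing for round-tripping.

On output, serial > 99999 or resSeq outside −999..9999 is a hard overflow
error; the writer's `renumber` option (and `clean`) regenerate serials
instead. Hybrid-36 encoding is intentionally out of scope.

## Parsing and parallelism

Parsing is tokenize-then-assemble. Tokenization (line → atom record /
control token / metadata / error) is pure per line, so the parallel mode
simply distributes line chunks over worker processes and concatenates the
token streams in file order; grouping into the hierarchy is always done
serially on that merged stream. Consequently parallel results are
bit-identical to serial ones by construction — the contract the tests
verify at 1/2/4/8 workers — rather than by careful synchronization.

Grouping rules: a residue breaks on (resName, resSeq, iCode) change or TER;
a chain breaks on chainID change or TER (a re-appearing chain id opens a
*new* chain object, preserving the record stream; a lint flags it); MODEL/
ENDMDL bracket models, a file without MODEL records gets one model with id
1, and coordinates appearing after ENDMDL are attached to a fresh implicit
model with a lint warning. Gzip input/output is keyed on the `.gz` suffix.

## Writer and normalization

Output order is head metadata, coordinate block (MODEL lines only for
multi-model structures, one TER after each chain containing polymer —
non-HETATM — residues, none after pure-water/ligand chains), tail metadata,
`END`. Metadata interleaved *inside* the original coordinate block is
re-emitted in the tail block: a known fidelity limit, accepted because
in-block metadata is rare and position-insignificant.

`clean` returns a copy whose written form strict-reparses with zero errors:
fields stripped/truncated to column width, blank single-character codes
defaulted, occupancy/B rounded to the format's two printed decimals, atom
serials regenerated with TER counted, unknown-record metadata dropped, and
(optionally) residues renumbered from 1 per chain. It is idempotent.

## Traversal

`count`, `map_over`, `fold_over` and `map_with_state` take an explicit
target-level argument and visit all nodes of that level in document order;
a node of the target level visits itself (singleton rule). `count` is
computed arithmetically from container lengths rather than by enumeration.
Folds are eager. LEFT folds call `fn(acc, node)` in document order; RIGHT
folds call `fn(node, acc)` from the last node backwards — the classical
foldl/foldr argument conventions, chosen so a non-associative operator
behaves exactly as list foldr on the document-order sequence. Maps return a
new root (unchanged sub-trees may be structurally shared); exceptions from
the visited function are re-raised as `TraversalError` carrying the node's
document-order position.

## Analyses

- **Center of mass** is two fold passes (weighted coordinate sum, then
  weight sum). The default weighting is UNIFORM — bead-model geometry in
  small-angle scattering is unweighted — with ELEMENT_MASS as an option
  using standard atomic weights; a missing or unknown element symbol under
  mass weighting is an error, never silently weight 1.
- **Radius of gyration**: √(Σwᵢ‖rᵢ−c‖²/Σwᵢ), translation- and
  rotation-invariant to ~1e-9 on desk-scale inputs.
- **Renumbering**: residues get consecutive numbers per chain with
  insertion codes cleared (consecutive numbering makes them meaningless);
  atom serials restart at 1 per model and each emitted TER consumes one
  serial. Both are stateful maps and idempotent.
- **Canonical axes**: translate the center to the origin; find the maximum-
  distance atom pair by an exact O(n²) scan (ties broken to the lowest
  document-order pair, the pair vector oriented to non-negative y) and
  rotate it onto +Y via Rodrigues' formula; then rotate about Y to bring
  the principal eigenvector of the XZ-projected second-moment matrix onto
  +X (eigenvector sign fixed to non-negative x; the step degenerates to the
  identity for collinear clouds). The moment-based cross-section was chosen
  over a max-extent (rotating-calipers) definition for robustness to single
  outlier atoms; both satisfy "widest cross-sectional direction" for
  generic clouds. The composed motion is returned as a `RigidTransform`
  (orthonormal, det +1, checked to 1e-9).
- **Sequences**: standard three-letter → one-letter amino-acid table plus
  one-letter nucleotide codes; common variants (MSE→M, SEC→U, PYL→O)
  included; waters skipped; anything else `X`.

## Synthetic data

The fixture generator emulates the *format-level* variety of archive
entries — multi-model ensembles, several chains, alternate locations,
water tails with HETATM records, and deliberately malformed lines (unknown
record names, non-numeric serials/coordinates) injected at seeded positions
outside the header. Coordinates are uniform in a ±99 Å box quantized to 3
decimals and occupancy/B to 2, so every fixture survives the text round
trip exactly. It does **not** emulate biophysical geometry (bond lengths,
angles, realistic sequences) or header-record semantics; passing tests
therefore demonstrate format fidelity, traversal correctness and numerical
correctness of the analyses, not biological plausibility of inputs.
Generation is driven by numpy's seeded PCG64 stream; if that stream ever
changed across platforms, frozen expectations would be regenerated rather
than pinned to bytes.

## Problem sizes and tolerances

The test suite and the acceptance script run entirely on synthetic inputs:
1000 random records for the codec round trip, 50 random recipes for the
structure round trip, one 100,000-atom file for the parallel/serial
equivalence check, 10,000 random byte strings for parser fuzzing, and a few
hundred atoms for the geometry properties — sizes at which every check is
exact or at floating-point noise level. Exact equality is asserted wherever
the contract is discrete (round trips at the format's printed precision,
error counts, serial sequences); geometric identities use 1e-9 and rigidity
1e-6, matching what double precision delivers with headroom.

## Known limitations

- In-block metadata placement is not preserved (see Writer).
- Chains split by TER or id change are never re-merged; consumers wanting
  merged chains must do so explicitly.
- No mmCIF, no header semantics, no connectivity, no anisotropic B-factors,
  no hybrid-36 serials, no structure superposition/RMSD.
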