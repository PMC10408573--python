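# Methods

## The representation and its guarantee

A SELFIES string is a finite sequence of bracketed symbols interpreted as
instructions to a derivation engine. The engine's state is a nonterminal
X_i: "the current attachment atom can accept at most i further units of bond
order", with a distinguished start state S and X_0 defined as the empty
string (the fragment is finished and remaining symbols are discarded). The
derivation rules are listed in `selgram/decoder.py`; the essential mechanism
is that every bond order is clamped to
`d0 = min(nu(new atom), i, d(bond prefix))`, where `nu` is the configured
valence function and `d` maps the prefixes `'' = #` to orders 1, 2, 3 (the
stereo prefixes `/` and `\` have order 1). Branch symbols reserve
`min(i - 1, d(beta))` at the parent before the payload is derived from state
X_{d0}; ring symbols only enqueue a closure candidate and reserve capacity
for it.

Ring closures are the one place a naive rule could break a valence, so they
are finalised after the fragment's symbols are exhausted, first-to-last:
each candidate recomputes the *actual* remaining capacities m1, m2 of its two
endpoints from the bonds present at that moment (including closures made by
earlier candidates), is rejected when either capacity is zero or the atoms
coincide (no self-loops), forms a bond of order `min(d(beta), m1, m2)`
otherwise, and promotes an existing bond to `min(3, d1 + d0)` when the pair
is already bonded (a duplicated ring symbol therefore raises the bond order).
Because the finalisation check — not the derivation-time reservation — is
what gates every ring bond, validity holds regardless of how the reservations
interact with branches.

Together these rules make decoding *total*: any well-formed symbol sequence,
including uniformly random ones, yields a molecule obeying the constraint
table. The test suite asserts this by fuzzing (random and adversarial symbol
mixes, custom constraint tables) against `check_valences`, an independent
oracle that recomputes every atom's incident bond order directly from the
bond list, and cross-checks output syntax and kekulized ring chemistry with
RDKit. Only lexical failures (unbalanced brackets, non-canonical atom
tokens such as `[N+]` or `[CH]`, an H count exceeding the valence) can make
decoding raise.

## Valence constraints

Constraints map (element, formal charge) to a maximum total bond order, with
a catch-all of 8 for unlisted atom types so lookups are total; explicit
hydrogens in an atom symbol decrement the remaining capacity, and isotope
labels share the element's valence. The default table (C 4/5/3 for
charges 0/+1/−1, N 3/4/2, O 2/3/1, B 3/2/4, P 5/6/4, S 6/7/5, monovalent
H/F/Cl/Br/I) targets organic molecules with single, double and triple bonds.
Charged halogens are not listed and resolve to the catch-all — the table
gives them no value, and resolving rather than rejecting preserves totality.

The named presets beyond `default` are configuration, not algorithm: this
package fixes
`octet_rule` as the default with non-hypervalent P (3/4/2) and S (2/3/1),
and `hypervalent` as the default plus 7-bond Cl/Br/I and 5-bond N. Setting
constraints replaces the active table entirely (no merging); zero capacities
are legal and produce isolated atoms.

## The index code and the symbol table

Symbols following a branch or ring symbol are reinterpreted as hexadecimal
digits through a fixed 16-entry symbol-to-index table (every unlisted symbol
is digit 0), and `l` of them encode `N = 1 + sum(c_k * 16**(l-k))` with
missing digits defaulting to 0 — so an index read never fails, even at the
end of a string. N is a branch payload length or a ring-closure offset
(`[Ring1]` + digit `[Ring2]` = offset 3: close to the 3rd preceding atom,
clamped to the fragment's first atom). The encoder uses the canonical digit
representatives and always emits the smallest `l` whose range covers the
value; offsets or payloads beyond 16^3 are an encoding error.

## Encoding and kekulization

The encoder parses SMILES to the same directed-graph representation the
decoder builds (atoms in traversal order; tree bonds parent→child; ring bonds
left→right), kekulizes if aromatic symbols are present, validates against the
active constraints, and then inverts the derivation rules symbol by symbol.
Each atom merges with its incoming bond token into one symbol; each non-final
child of an atom becomes a branch whose connecting bond token appears both on
the branch symbol (reserving parent capacity) and on the payload's first atom
symbol (realising the bond order under the derivation rules — without the
duplicate prefix a double-bonded branch such as the carbonyl in `CC(=O)O`
could not round-trip). Ring symbols are emitted at the atom where the input
closed the ring, in input digit order. A capacity argument guarantees the
decoder re-realises every emitted bond at full order: since the input graph
passed validation, at every derivation point the head's remaining state is at
least the sum of the bond orders still to be placed there.

Kekulization decides which aromatic atoms need a double bond from a small
aromatic valence model (B 3, C 4, N 3, O 2, P 3, S 2, shifted by the formal
charge): an atom with leftover valence after its sigma bonds and hydrogens
needs exactly one. That is a perfect-matching problem on the aromatic
subgraph, solved with networkx's maximum-cardinality matching (exact blossom
algorithm, so a Kekulé assignment is found whenever one exists); matched
bonds become double, flags are cleared, and failure (e.g. an odd carbon
cycle) raises a kekulization error. Aromaticity *perception* of Kekulé input
is deliberately out of scope: output is always Kekulé-form.

## Hydrogen-count and equality conventions

SMILES bracket atoms without an H digit store an explicit count of 0;
SELFIES decorated tokens may omit the H part entirely. Graph equality
treats these as the same atom once written in bracket form (neither adds
hydrogens) but keeps bare organic-subset atoms — whose hydrogens are
implicit — distinct from an explicit `H0`. The token `[CH0]` therefore
exists and is distinct from `[C]`, while `[O-1]` needs no `H0`. String-level
identity through a round trip is *not* guaranteed (e.g. `[13CH]` re-emerges
as `[13CH1]`, `%12` ring tags renumber); molecule and traversal order are.

## Attribution

Both translation directions can annotate every output token with the input
tokens responsible: atom tokens map to their atom symbol (and the demoted
bond token to the symbol that carried the prefix), branch parentheses to the
branch symbol plus its index digits, ring tags to the ring symbol plus its
digits; in the encode direction a branch symbol traces to the opening
parenthesis and the branch's first atom. Input that produces no output —
padding, symbols discarded after X_0, branch/ring symbols skipped at S or
X_1, rejected ring closures — is reported in a separate `unconsumed` list
rather than silently dropped. The output string is bitwise identical with
or without attribution.

## Design choices where the rules left room

* A branch or ring symbol skipped at S or X_1 consumes only itself; its
  would-be index and payload symbols are processed as ordinary symbols.
  Either convention preserves robustness; this one discards less input.
* An empty branch payload still reduces the parent state by the reserved d0.
* The dot splits a string into independently derived fragments; fragments
  that decode to nothing are dropped when joining, so the output is never an
  invalid string like `"C."`. The homomorphism
  `decode(A + "." + B) = decode(A) + "." + decode(B)` therefore holds
  whenever both sides decode to non-empty fragments.
* Ring closures across a dot in SMILES input are rejected as unsupported:
  fragments are independent derivations and cannot express them.
* SMILES ring tags are surface syntax: the writer allocates the smallest
  free number, reuses numbers after closure, and switches to `%nn` from 10.
  Bond orders above 1 on a ring closure are written at both tag positions;
  stereo ring markers are written on the tag of the endpoint that carries
  them. Promoting a bond above order 1 drops its stereo markers, which only
  decorate single bonds.
* The unicode minus occasionally found in stereo ring tokens (`[/−Ring1]`)
  is normalised to ASCII `-` at parse time; everything else non-canonical is
  rejected, not normalised.

## Scales, defaults and limitations

The robustness experiments use 1,000 strings of 20 uniform symbols for the
headline validity percentage and 10,000
strings of length 5–100 with adversarial symbol mixes for the extended fuzz;
the growth experiment uses 1,000 strings per condition at lengths 10/30/100.
All samplers take explicit seeds and sort the alphabet first, so results are
reproducible and independent of set iteration order.

Random sampling is a study of the representation, not of chemistry: uniform
symbol draws produce exotic charged species (e.g. `[P+1]`, `[C-1]`) that are
valence-consistent but not synthetically meaningful, and the growth trend
says nothing about drug-likeness. Known limitations: no wildcard `*` or
quadruple-bond `$` atoms, no extended chirality tags (`@TH1`, ...), no
aromatic output, no cis/trans consistency checking (stereo tokens are
carried faithfully but not validated), no canonical SMILES generation, and
the catch-all of 8 may be too lax for heavy elements — users working with
such species should set explicit constraints.
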