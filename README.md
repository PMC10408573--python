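# selgram

A robust molecular string representation for cheminformatics and generative
molecular design: every finite sequence of symbols decodes to a syntactically
and semantically valid molecule.

SMILES, the de-facto standard string representation of molecules, is fragile
in machine-learning settings: generative models routinely emit strings with
unmatched parentheses or ring numbers (syntactic errors) or with atoms
exceeding their chemical valences (semantic errors, e.g. the trivalent oxygen
in `CO=C`). SELFIES (self-referencing embedded strings) removes both failure
modes at the representation level. Its symbols are instructions to a small
context-free grammar augmented with self-referencing branch and ring
functions; a nonterminal state X_i tracks the remaining bond capacity of the
current attachment atom, and every bond is demoted to the highest order
`d0 = min(nu(atom), i, d(beta))` that the valence function nu still permits.
Ring closures are deferred to a finalisation pass that rejects or demotes any
closure that would break a valence. As a consequence *any* symbol sequence —
including uniformly random ones — maps to a molecule satisfying the
configured constraints, which makes the representation directly usable as a
latent space for generative models, genetic algorithms and random sampling.

`selgram` implements the full representation as a pure-Python library:

* `decode` / `encode` — translation between SELFIES and (Kekulé) SMILES,
  with the round-trip guarantee `decode(encode(s))` ≡ same molecule, same
  atom traversal order; the encoder kekulizes aromatic input internally
* configurable valence constraints (`preset_constraints`,
  `configure_constraints`) mapping (element, charge) to maximum bond counts,
  with a catch-all entry and `default` / `octet_rule` / `hypervalent` presets
* token attribution (`translate_attributed`) connecting every output token
  to the input token(s) responsible for it, in both directions
* utilities: `len_selfies`, `split_selfies`, alphabet extraction, label and
  one-hot encodings for ML pipelines, the semantically robust sampling
  alphabet (69 symbols under the default constraints) and a uniform random
  sampler of valid molecules
* a `selgram` command-line tool (`encode`, `decode`, `roundtrip`, `sample`,
  `alphabet`, `attribute`, `check`)

## Worked example

```python
>>> import selgram
>>> selgram.decode("[C][O][=C][F]")        # '=' demoted: O has 1 bond left
'COCF'
>>> selgram.decode("[O][C][Branch1][C][O][C]")   # acetic acid
'OC(O)C'
>>> selgram.decode("[C][C][C][C][C][Ring1][Ring2]")  # methylcyclobutane
'CC1CCC1'
>>> selgram.encode("C(O)O")                # minimal branch/index symbols
'[C][Branch1][C][O][O]'
>>> selgram.encode("c1ccccc1")             # aromatic input is kekulized
'[C][=C][C][=C][C][=C][Ring1][=Branch1]'
>>> selgram.decode(selgram.encode("c1ccccc1"))
'C1=CC=CC=C1'
```

Random sampling never produces an invalid molecule:

```python
>>> from selgram import get_semantic_robust_alphabet, sample_random_selfies, decode
>>> alphabet = sorted(get_semantic_robust_alphabet())   # 69 symbols
>>> sample_random_selfies(alphabet, length=10, count=1, seed=5)
['[=P-1][Branch2][S-1][#Branch2][O][=P+1][#C-1][=Branch1][#S+1][C+1]']
>>> decode(_[0])
'[P-1]O[P+1]#[C-1]'
```

The decoded string is short because multi-bond and low-valence symbols
exhaust the available valences quickly; sampling from the 19-symbol filtered
alphabet (`get_chain_growth_alphabet`) instead yields molecules that keep
growing with the string length.

On the command line:

```sh
$ selgram decode "[C][O][=C][F]"
COCF
$ selgram alphabet --count
69
$ selgram check "CO=C"
CO=C	INVALID	atom 1 makes 3 bonds (max 2)
```

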