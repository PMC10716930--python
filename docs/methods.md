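# Methods

This note documents the models, algorithms, defaults and numerical choices
behind patgen, and what the synthetic test universe does and does not show
about behaviour on real patent-chemistry data.

## Structure identity

Every module agrees on one notion of structural identity: the 27-character
InChIKey of the standardized parent structure computed **after erasing all
stereochemistry**. Standardization follows the ChEMBL-style ruleset as
implemented by RDKit's `rdMolStandardize`: functional-group normalization,
retention of the largest organic fragment (desalting), and charge
neutralization. Records with no carbon-containing fragment are rejected —
they can serve neither as training data nor as reward-lookup subjects.

Stereochemistry is removed from the *structure* before key generation rather
than truncating keys to their connectivity block, so full 27-character keys
remain comparable and stereoisomers collide by design. Rationale: patent
structure extraction is unreliable about stereo descriptors, and a membership
oracle that distinguished enantiomers would under-count patent coverage.
Tautomer canonicalization is deliberately out of scope; two tautomers drawn
differently are treated as different structures.

## Drug-patent database

A patent is *drug-related* iff any IPC or CPC code, uppercased and stripped,
starts with `A61K` (medicinal preparations) or `A61P` (therapeutic activity)
— a four-character subclass prefix match. Compounds linked to at least one
drug-related patent survive; optionally, structures that originate from
automated image recognition (OCR) are removed, since they carry a high error
rate. Survivors are standardized and stored as `(inchikey, external_id)`
rows in a single-file SQLite table with an index on the key column.
Duplicate keys are kept (distinct accessions may standardize to the same
structure); distinct-key counts are reported separately. Patent numbers stay
in the JSON build report, not in the hot lookup table. Every filter stage
reports its count, so no record is ever dropped silently.

## Exact-structure matchers

Three interchangeable engines answer "is this exact structure in the
database?":

* **inchikey** — text equality against the indexed SQLite table.
* **mhfp6_lsh** — 2048-permutation MHFP6 minhash vectors (RDKit's built-in
  encoder, fixed permutation seed) in a banded LSH index: the 2048 positions
  are split into 32 contiguous bands of 64; identical vectors collide in
  every band, so candidate recall for true exact matches is exactly 1.
  Retrieved candidates are ranked by estimated Jaccard (fraction of agreeing
  minhash positions) and the top *k* (default 10) are verified.
* **morgan_bruteforce** — maximum Tanimoto over Morgan radius-3 2048-bit
  fingerprints; a match requires similarity exactly 1.0.

Both fingerprint engines verify candidates by InChIKey equality, so a
fingerprint collision can never produce a spurious exact match: the three
engines agree on any input by construction and differ only in latency.
Benchmark timing covers the query phase only; reference preparation (DB
build and indexing, LSH construction, reference fingerprints) is reported
separately and never added. At reference sets of 10^5 molecules the
query-latency ordering inchikey < mhfp6_lsh < morgan_bruteforce is robust;
absolute times are hardware-dependent and are reported, not asserted.

## Corpus curation

Training data for the language model passes through an ordered pipeline:
(1) seeded subsample; (2) drop empty/unparseable SMILES; (3) drop ringless
molecules; (4) drop molecules with elements outside {H, B, C, N, O, F, Si,
P, S, Cl, Br, I}, any isotope label, or any blacklisted substructure;
(5) desalt to the largest organic fragment; (6) drop molecules outside
per-descriptor quantile bands computed on the post-desalt population for
atom count, heavy-atom count, molecular weight, SlogP, aromatic-ring count
and fraction Csp3; (7) seeded final subsample; (8) standardize and emit
canonical SMILES. The default tail quantiles are (0.005, 0.995) per side —
upstream collections differ in what counts as "atypical", so this is config,
and exact corpus reproduction against a particular source requires that
source's thresholds. The default blacklist is a short list of reactive
groups (acyl halide, isocyanate, peroxide, N-nitroso, azide, non-benzylic
alkyl halide); it is likewise replaceable config. All stages report counts;
identical input, config and seed give a byte-identical corpus file. Note
that stages (1)–(5) are per-molecule rules and are a fixed point under
re-curation; the quantile stage is population-relative and is not.

## Language model

A 2-layer GRU over SMILES tokens: embedding (default 32–64 dims) → GRU
(hidden size configurable) → softmax head. Tokenization is lossless;
multi-character element symbols (Cl, Br), bracket atoms and `%nn` ring
closures are single tokens. Sequences are start-prefixed, end-terminated and
pad-filled to the longest corpus sequence. Training minimizes next-token
cross-entropy with Adam; dropout uses a per-sequence (variational) mask on
each GRU layer's output. After the end symbol the next-token distribution is
defined as a point mass on the pad symbol.

The model, backpropagation through time and the optimizer are implemented
directly in NumPy. This keeps the package dependency-light and bit-exact
under a seed; a finite-difference gradient check in the test suite guards
the hand-derived gradients. The shipped default hyperparameters — dropout
0.1077, learning rate 4.34e-4, batch size 384, hidden units 896, 500 epochs,
10% validation — are the reference configuration for a ~250k-molecule
patented-compound corpus with padding length 109 (recomputed per corpus).
Desk-scale work and the test suite use a reduced instance (hidden 96,
30 epochs on a 2,000-molecule corpus, ~1 minute on one CPU) that reaches
≥50% syntactically valid unconditional samples; production-scale models
reach far higher. Layer count (2) and the optimizer (Adam) are package
choices recorded here, not searched values. Checkpoints round-trip
bit-compatibly through `.npz` + JSON.

## Tree search

The generator runs UCT Monte-Carlo tree search over token prefixes:

* **Selection**: descend by `W/N + C * sqrt(2 ln N_parent / N_child)`;
  unexpanded tokens take priority; ties break to the lowest token index.
* **Expansion**: child tokens are those whose model probability at the node
  exceeds a pruning threshold (default **0.02**), tried in order of
  descending prior. The threshold matters: with a sparse binary reward the
  tree's Q-values are near zero everywhere, so the exploration bonus
  dominates and a permissive threshold (say 1e-4) makes the search expand
  ~20 mostly implausible tokens per node — measured validity collapses to
  1–2%. At 0.02 the tree stays inside the model's plausible continuations
  and validity tracks the model's unconditional validity.
* **Rollout**: sample token-by-token from the model (temperature 1.0)
  starting from the node's cached hidden state.
* **Evaluation**: parse → standardize → descriptors → five filters; the
  reward is computed only for parse-valid, filter-passing molecules.
  Filtered and invalid proposals backpropagate 0 by default
  (`filtered_reward_mode="zero"`; `"skip"` omits backpropagation entirely).
* **Terminal exhaustion**: a terminal node (end token or maximum length)
  represents exactly one molecule; after its single evaluation it is marked
  exhausted and selection never re-enters it, and an inner node whose
  children are all exhausted closes too. Without this the search re-proposes
  its best reward-1 molecules indefinitely and the valid-unique count grows
  only logarithmically in iterations (measured: 821 unique molecules in
  400,000 iterations; with exhaustion, 3,000 unique in ~7,000). The reward
  signal still reaches ancestors through the one-time backpropagation, so
  node means estimate the density of rewarding molecules in each subtree.

Every proposed SMILES — valid or not — is appended to the generation log in
proposal order. Budgets: wall-clock seconds, a target count of
valid-and-unique molecules (the protocol used for run comparisons), or an
iteration cap.

### Rewards

`r_patent(x)` is 1 iff the stereo-free key of x is in the database, else 0;
`r_not_patent` is its complement; `r_rand` draws uniform [0, 1) values from
a seeded stream, independent of the molecule, as an indifferent baseline.

### Generation filters

Five per-molecule screens, individually switchable: a configurable
rare-pattern substructure list (default: the reactive-group list plus
allene, disulfide and acyclic azo motifs — standing in for a corpus-derived
pattern-frequency table, which is replaceable config); Lipinski's rule of
five (fail iff MW > 500 or SlogP > 5 or H-bond donors > 5 or acceptors >
10); radicals (any unpaired electron); synthetic accessibility ≥ 3.5; and
any ring larger than 6 atoms.

## Synthetic-accessibility score

The fragment-contribution method: mean per-fragment commonness score over
the molecule's Morgan radius-2 environments, minus complexity penalties
(size `n^1.005 - n`, stereo centres, spiro atoms, bridgeheads, macrocycles)
plus a symmetry correction, mapped to 1 (easy) … 10 (hard). Fragment scores
come from a frequency table over a reference population:
`clip(2.3 + log10(count / c_ref), -4, 4)` with `c_ref` the count at 80%
cumulative fragment mass; unseen fragments score −4.

The default table is built once per process from a deterministic in-package
reference enumeration of common medicinal-chemistry motifs (plus reactive
reagents, radicals, medium rings and large flexible amides, which real
reference populations also contain, and a strided sample of the package's
own plain-chemistry enumeration families). Consequences to be aware of:
absolute values are not comparable to PubChem-derived tables, and chemistry
far from the reference population scores uniformly hard. The ordering that
the ≥3.5 generation filter relies on — ordinary substituted-ring chemistry
well below 3.5, cages/spiro systems well above — is calibrated and tested.
`build_fragment_scores` accepts any corpus for callers who want a table
grounded in their own data.

## Analysis metrics

Validity = (parse-valid **and** filter-passing proposals) / all proposals —
the combined notion, stricter than parse-validity alone. Uniqueness =
distinct canonical SMILES among valid proposals / valid proposals. Database
match counts deduplicate by canonical SMILES first and, when comparing runs,
are restricted to the first K valid-unique molecules in proposal order.
Similarity is the Tanimoto coefficient of Morgan radius-2 2048-bit
fingerprints; "max similarity" distributions bin at 0.05 with left-closed,
right-open bins and a closed top bin (1.0 falls in [0.95, 1.00]).
Drug-likeness is RDKit QED. Chemical-space projection is UMAP on the binary
fingerprint matrix under a Jaccard metric with a fixed random state
(deterministic per seed). Analog reports list generated molecules with
similarity ≥ 0.5 (configurable) to a query drug, each annotated with
similarity, QED, and whether the analog itself is in the database.

## Synthetic universe (fixtures)

The fixture module enumerates scaffold × substituent combinations (11 ring
templates, 14 default substituents, up to 3 substitutions), canonicalizes,
deduplicates by stereo-free key, shuffles with a seed and truncates —
default 5,000 molecules, of which 60% are assigned to synthetic A61K/A61P
patents and the rest to non-drug C07D patents, with a 10% OCR-flag rate.
Enumeration (not random mutation) keeps ground-truth membership exact and
platform-stable. A larger substituent set provides the ~10^5-molecule space
for the matcher benchmark.

What the universe does **not** emulate: the property distributions, scaffold
diversity, salt forms, stereo annotations and OCR error modes of real
patent-chemistry exports. Passing tests demonstrate algorithmic correctness
(membership logic, engine agreement, steering direction, metric formulas),
not performance on real extraction noise. Scale is also deliberately small:
desk-scale studies use a 5,000-molecule universe, a 2,000-molecule training
corpus, 30 training epochs and 3,000-molecule generation budgets per run,
sizes chosen so the full pipeline runs in minutes on one CPU; headline
numbers from production-scale runs (10^7-compound databases, 250,000-molecule
budgets, 24-hour GPU searches) are far outside these conditions, so the
package's checks are directional and structural rather than numerical
reproductions of that regime.

## Determinism

Every stochastic step — universe enumeration order, partition, corpus
sampling, weight initialization, dropout, training shuffles, rollouts, the
random reward, UMAP — flows from explicit seeds recorded in configs and
provenance JSON. Identical inputs and seeds reproduce logs byte-for-byte.

## Known limitations

* Membership is structure-level presence in patents, not a legal
  patentability judgement (no claim analysis, no legal status).
* Stereo- and tautomer-insensitive identity can over- and under-count
  coverage respectively.
* The NumPy GRU trains on CPU; paper-scale configurations (hidden 896, 500
  epochs, 250k sequences) are supported by the code but impractical without
  substantial compute.
* The SA table and rare-pattern list are package defaults, not derived from
  a public compound corpus; both are injectable.
* Single-objective rewards only; composing patent membership with activity
  or ADMET models is future work.
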