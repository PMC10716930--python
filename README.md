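# patgen — patent-aware de novo molecular generation

Generative molecular design usually optimizes potency, drug-likeness or
synthesizability and ignores a question every medicinal chemistry project
eventually faces: *is this structure already claimed in someone's patent?*
patgen makes patent membership a first-class, machine-checkable signal
during generation. It is a library (plus a thin `patgen` CLI) for
computational chemists who want to steer a SMILES generator either **into**
patented chemical space (to mine analog series around claimed compounds) or
**away from it** (to search for potentially unclaimed chemistry).

The pipeline:

1. **Drug-patent database** — from patent-compound records (compound SMILES
   + patent numbers; patent numbers + IPC/CPC codes), keep compounds linked
   to drug-related patents (codes starting `A61K`/`A61P`), drop error-prone
   OCR-extracted structures, standardize/desalt, and store stereo-free
   InChIKeys with their accessions in an indexed SQLite file.
2. **Exact matching** — three interchangeable engines (InChIKey text lookup;
   MHFP6 minhash + banded LSH with verification; Morgan radius-3 brute-force
   Tanimoto with verification) that provably agree and differ only in speed.
3. **Language model** — a 2-layer GRU over SMILES tokens (NumPy
   implementation, seeded and bit-reproducible) trained on a corpus curated
   from the patented compounds.
4. **Generation** — UCT Monte-Carlo tree search over token prefixes,
   `W/N + C·sqrt(2 ln N / N_i)`, with rollouts from the model, five
   generation filters (rare patterns, Lipinski, radicals, synthetic
   accessibility ≥ 3.5, rings > 6), and plug-in rewards:

   ```
   R_patent(x)     = 1 if x is in the drug-patent DB else 0
   R_not-patent(x) = 1 - R_patent(x)
   R_rand(x)       ~ Uniform[0, 1)          (seeded baseline)
   ```

5. **Analysis** — validity and uniqueness (validity counts parseable *and*
   filter-passing strings; uniqueness is distinct/valid), DB match counts,
   max-Tanimoto similarity distributions, QED, UMAP chemical-space maps and
   analog reports around query drugs.

A deterministic synthetic patent universe (enumerated scaffold × substituent
molecules with an exactly known patented/unpatented split) stands in for
bulk patent-chemistry exports, so the whole pipeline runs and is tested
offline in minutes. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

`examples/04_generate_with_rewards.py` builds a 5,000-molecule universe
(60% patented), trains the GRU for 30 epochs on 2,000 patented compounds,
then runs the search with each reward at C = 0.4 until 3,000 valid-unique
molecules (seeded, so your numbers will match):

```
R_patent      validity 0.63  uniqueness 0.70  DB matches among first 3000 unique: 295
R_rand        validity 0.80  uniqueness 0.66  DB matches among first 3000 unique: 244
R_not-patent  validity 0.84  uniqueness 0.45  DB matches among first 3000 unique: 37
```

Reading the numbers: validity and uniqueness are properties of the language
model and search mechanics, so they stay in the same band for all three
rewards. The DB match count is what the reward controls — the patent reward
raises the match count well above the indifferent baseline, and its
complement suppresses matches severalfold. The other example scripts cover database
construction, engine agreement/latency, corpus curation + training, and the
post-run analytics (similarity, QED, analogs, UMAP), each printing a short
interpretation of its output.

## Layout

```
src/patgen/
  chemstd.py     structure parsing, standardization, stereo-free InChIKeys,
                 descriptors, fingerprints, Tanimoto
  sa_score.py    synthetic-accessibility score + fragment table construction
  patentdb.py    drug-related classification rule, DB build/lookup/stats
  matchers.py    the three exact-match engines + latency benchmark
  corpus.py      staged training-corpus curation with audit counts
  langmodel.py   SMILES tokenizer, NumPy GRU, training, sampling, checkpoints
  generator.py   rewards, generation filters, UCT tree search, logs
  analysis.py    metrics, similarity/QED distributions, UMAP, analog search
  fixtures.py    deterministic synthetic patent universe
  cli.py         patgen fixtures|build-db|curate|train|generate|match-bench|analyze
examples/        one narrative script per capability
```
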