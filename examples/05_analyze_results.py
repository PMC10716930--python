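"""Post-generation analytics: similarity, drug-likeness, analogs, projection.

Takes a generation log and asks the questions that matter after a run: how
close are the new molecules to the training compounds (novelty), how
drug-like are they (QED), which ones are analogs of a query structure, and
where do they sit in a 2-D chemical-space projection.
"""

from pathlib import Path

from patgen import analysis, chemstd, fixtures, generator, langmodel, patentdb

spec = fixtures.FixtureSpec(n_target=3000, seed=21)
universe = fixtures.make_universe(spec)
split = fixtures.split_universe(universe, frac_patented=0.6, seed=22)
db = patentdb.build_db(list(split.patented), split.patents, exclude_ocr=False)

corpus = fixtures.make_corpus(split.patented, 1500, seed=23)
hp = langmodel.LMHyperParams(
    dropout=0.1, learning_rate=1e-3, batch_size=64, hidden_units=96,
    epochs=30, validation_fraction=0.1, seed=24, embedding_dim=32,
)
model = langmodel.train_lm(corpus, hp)
log = generator.mcts_generate(
    model, generator.r_patent(db),
    generator.GenerationConfig(
        c_explore=0.4, seed=25,
        budget=generator.Budget(target_valid_unique=400, max_iterations=20_000),
    ),
)

gen = [chemstd.standardize_smiles(s) for s in log.valid_unique_smiles()[:400]]
train = [chemstd.standardize_smiles(s) for s in corpus[:400]]

dist = analysis.max_similarity_distribution(gen, train)
print(f"max-similarity to training set: {100*dist.fraction_eq_1:.1f}% exact, "
      f"{100*dist.fraction_ge_07:.1f}% at >= 0.7")
peak = dist.bin_edges[dist.counts.argmax()]
print(f"distribution peak in bin [{peak:.2f}, {peak+0.05:.2f})")

qed = analysis.qed_distribution(gen[:200])
print(f"QED mean {qed['mean']:.2f}, median {qed['median']:.2f}")

# scan a few claimed compounds and report the one with the richest analog
# series among the generated molecules
drug, hits = max(
    ((e.smiles, analysis.find_analogs(log, e.smiles, threshold=0.5, db=db))
     for e in split.patented[:25]),
    key=lambda pair: len(pair[1]),
)
print(f"analogs of {drug} at similarity >= 0.5: {len(hits)}")
for h in hits[:3]:
    star = "*" if h.db_match else " "
    print(f"  {star} sim {h.similarity:.2f}  QED {h.qed:.2f}  {h.smiles}")

emb = analysis.embed_chemical_space(gen[:150], train[:150], seed=0)
Path("scratch").mkdir(exist_ok=True)
analysis.plot_embedding(emb, "scratch/chemspace.png")
print("UMAP projection written to scratch/chemspace.png "
      f"({emb.coordinates.shape[0]} points)")

# High exact-match and >=0.7 fractions are expected here: the R_patent
# reward deliberately steers the search back into patented chemistry.
# Asterisked analogs are themselves patented compounds.
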