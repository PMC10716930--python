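"""Build a drug-patent database from patent-compound records.

Generates a small synthetic patent universe (a stand-in for a bulk
patent-chemistry export), keeps only compounds linked to drug-related
patents (IPC/CPC codes A61K*/A61P*), standardizes them and stores their
stereo-free InChIKeys in an indexed SQLite file.
"""

from pathlib import Path

from patgen import fixtures, patentdb

Path("scratch").mkdir(exist_ok=True)

spec = fixtures.FixtureSpec(n_target=1000, seed=7)
universe = fixtures.make_universe(spec)
split = fixtures.split_universe(universe, frac_patented=0.6, seed=8)

db = patentdb.build_db(
    list(split.patented) + list(split.novel),
    split.patents,
    path="scratch/drugpatent.sqlite",
    exclude_ocr=True,
)

print("build report stage counts:")
for stage, count in db.build_report["stage_counts"].items():
    print(f"  {stage:28s} {count}")
print("db stats:", db.stats())

# membership of one patented and one novel molecule
patented = fixtures.as_standard(split.patented[:1])[0]
novel = fixtures.as_standard(split.novel[:1])[0]
print("patented molecule lookup ->", db.lookup(patented.inchikey_nostereo).matched)
print("novel molecule lookup    ->", db.lookup(novel.inchikey_nostereo).matched)

# The stage counts show how many compounds were dropped at each filter
# (non-drug patents, OCR structures, standardization failures); the lookups
# demonstrate the key-indexed membership oracle used by the reward functions.
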