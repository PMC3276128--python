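"""Narrow candidate regions from overlapping deficiencies.

A deficiency that modifies the phenotype places the responsible gene inside
its possibly-deleted region; one that does not excludes its certainly
deleted bands (breakpoint bands are kept — they may be only partially
deleted). Intersecting and subtracting these intervals pins the gene down
to a few polytene bands.
"""

from ndjscreen import candidate_region, datasets

table = datasets.region_mapping()
for name, group in table.groupby("region"):
    positives = group.loc[group.effect == "positive", "breakpoints"].tolist()
    negatives = group.loc[group.effect == "negative", "breakpoints"].tolist()
    region = candidate_region(positives, negatives)
    print(f"region {name}: {len(positives)} positives, {len(negatives)} negatives"
          f" -> candidate interval {region}")

print(
    "\nThe 77B interval is the region whose dosage reduction suppresses the\n"
    "nondisjunction phenotype (it contains the polo kinase locus); the other\n"
    "two come from the enhancer and embryonic-lethality follow-up crosses."
)
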