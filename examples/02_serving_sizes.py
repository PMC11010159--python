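"""Estimate standard serving sizes from observed consumption.

A "serving" of a category is the median consumed amount per age group and
eating occasion; sparse cells (fewer than 10 events) borrow the median of
the other occasions.  Prints the fruit-puree serving cells with their
provenance — the pouch (90 g) / cup (100 g) range is the sanity anchor.
"""

from dietshift import GeneratorConfig, build_serving_table, generate_dataset

dataset = generate_dataset(GeneratorConfig(n_children=500), seed=1)
table = build_serving_table(dataset)

frame = table.to_frame()
puree = frame[frame["category"] == "fruit_puree"]
print(puree.to_string(index=False))
print("\n'estimated' cells are cell medians; 'fallback' cells had fewer than "
      "10 events and use the other occasions' median instead.")
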