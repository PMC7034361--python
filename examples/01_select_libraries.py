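"""Select atlas-worthy libraries from messy run metadata.

Simulates a small compendium whose RunInfo and key-value metadata carry
realistic defects (variant key spellings, missing sex, single-end runs),
then applies the technical gate and descriptor harmonization.
"""

from coexatlas import (
    AtlasDesign,
    harvest,
    records_from_runinfo,
    simulate_expression,
    simulate_metadata,
)

design = AtlasDesign(seed=7, messiness=0.2)
truth = simulate_expression(design)
meta = simulate_metadata(design, truth)

records = records_from_runinfo(meta.runinfo)
metadata = {}
for run, key, value in meta.metadata.itertuples(index=False):
    metadata.setdefault(run, []).append((key, value))

descriptors, report = harvest(records, metadata)

print(f"{len(records)} candidate runs")
print(f"kept {len(report.kept)}, rejected {len(report.rejected)} "
      f"(reasons: {report.reasons()})")
print(f"generator injected: {meta.injected}")
first = report.kept[0]
d = descriptors[first]
print(f"example descriptor for {first}: tissue={d.tissue}, breed={d.breed}, "
      f"sex={d.sex}, age={d.age}")
# Every SINGLE-layout injection must appear as a 'layout' rejection; kept runs
# carry a harmonized tissue label, which the atlas grouping step requires.
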