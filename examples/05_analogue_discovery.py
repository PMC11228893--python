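"""Discover 18S-analogue regions in a toy assembly and write them as BED.

Plants two mutated copies of a query in a random subject sequence, recovers
them with the ungapped seed-and-extend search, and round-trips the result
through the BED writer/reader used by the counting pipeline. On real data the
query is the 18S subunit (unit positions 3,658-5,526) and the subjects are the
assembly contigs that harbor rDNA analogues.
"""

import io

import numpy as np

from ribocn.reference_prep import (
    RdnaUnitSequence,
    extract_18s_query,
    find_analogue_regions,
    loop_rdna_reference,
    read_region_bed,
    write_region_bed,
)

rng = np.random.default_rng(5)
unit_seq = "".join(rng.choice(list("ACGT"), size=6_000))
unit = RdnaUnitSequence("toy_unit", unit_seq)

query = extract_18s_query(unit, 3_658, 5_526)
print(f"query length        : {len(query)} bases (18S subunit span)")

looped = loop_rdna_reference(unit, breakpoint_upstream_of_tss=2_120)
print(f"looped reference    : {len(looped)} bases, rotation of the unit "
      f"(residues preserved: {sorted(looped) == sorted(unit_seq)})")

subject = list(rng.choice(list("ACGT"), size=20_000))
for pos in (3_000, 12_000):
    copy = list(query)
    for site in rng.choice(len(copy), size=len(copy) // 100, replace=False):
        copy[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[site]]
    subject[pos : pos + len(copy)] = copy
regions = find_analogue_regions(query, {"chr21_toy": "".join(subject)},
                                min_identity=0.95, min_length=100)
print(f"analogues found     : {len(regions)} (planted 2, ~1% substitutions each)")
for iv in regions:
    print(f"  {iv.contig}:{iv.start}-{iv.end}")

buffer = io.StringIO()
write_region_bed(regions, buffer)
buffer.seek(0)
assert read_region_bed(buffer) == regions
print("BED round trip      : ok")
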