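"""Build the default synthetic integrant genome and inspect its truth set.

The engineered allele carries one intact construct copy, a truncated copy
lacking the GS and HC cassettes, two extra LC copies (one inverted), a 240 bp
fragment borrowed from a second host contig, and a 4-fold amplified upstream
region.  Every junction and cassette copy number is known exactly.
"""

import insertmap as im

scenario = im.default_scenario(seed=1)

print("reference records (mapping targets):")
for rec in scenario.reference:
    print(f"  {rec.id:12s} {len(rec):>7,} bp  role={rec.role}")

print("\nengineered genome (read source):")
for rec in scenario.integrant:
    print(f"  {rec.id:18s} {len(rec):>7,} bp  copies={rec.copies}")

print("\ntruth junctions (breakend pairs; L = retained left of pos, R = right):")
for j in scenario.truth.junctions:
    print(
        f"  {j.a.ref_id}:{j.a.pos}{j.a.side} | {j.b.ref_id}:{j.b.pos}{j.b.side}"
        f"  ({j.orientation})"
    )

print("\ntruth cassette copy numbers:", scenario.truth.cassette_copies)
print("amplified-region fold over the diploid baseline:", scenario.truth.amplified_fold)
# The 7 junctions are the evidence the read-level analysis must recover;
# the copy numbers are what the depth analysis must call.
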