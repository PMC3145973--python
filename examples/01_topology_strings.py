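"""Topology strings: parsing, canonical form and fold comparison.

A fold is written as whitespace-separated tokens <dir><layer><slot>, e.g.
"+B+0" for the first sheet strand.  Canonicalization removes the arbitrary
labelling choices (position offsets, global direction, which helix layer is
"A") so that two encodings of the same fold compare equal.
"""

import foldbench as fb

a = fb.parse_topology("+B+0 -B+1 +A+0 +B+2")
b = fb.parse_topology("-B+5 +B+4 -A-2 -B+3")  # same fold, relabelled

print("a              :", a)
print("b (raw)        :", b)
print("b (canonical)  :", fb.canonicalize(b))
print("same fold      :", fb.same_fold(a, b))

c = fb.swap_sheet_positions(a, 0, 1)
print("strand swap    :", c)
print("edit distance a->c:", fb.edit_distance(a, c))
# The swap exchanges two sheet slots: one unit edit, so the distance is 1,
# while a and b are the identical fold (distance 0).
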