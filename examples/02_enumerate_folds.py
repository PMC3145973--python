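"""Enumerate all topologically distinct folds on a small ideal form.

A form n_A-n_B-n_C gives the lattice slots available per layer.  Every
assignment of the chain's SSEs to slots and directions is generated, folds
with left-handed parallel beta crossovers or crossing loops are filtered
out, and the survivors are deduplicated under canonicalization.
"""

import foldbench as fb

form = fb.Form(1, 3, 1)
folds = fb.enumerate_folds(form, n_helices=2, n_strands=3)
print(f"{form.name} form, 3 strands + 2 helices: {len(folds)} distinct folds")
print("first three:")
for ts in folds[:3]:
    print("  ", ts)

# A single strand has no permutation freedom at all:
print("single strand:", [str(t) for t in fb.enumerate_folds(form, 0, 1)])
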