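"""Folding, rare fractions and hypergeometric projection of an SFS.

Builds a small unfolded spectrum, folds it onto minor-allele counts, and
projects it to a smaller sample, printing the rare-variant fraction (minor
count <= 2) at each step.
"""

import numpy as np

from ratesfs import (
    SpectrumUnfolded, fold, fraction_rare, project, projection_masses,
)

# an unfolded spectrum for 12 chromosomes: mostly singletons, a few common
counts = np.array([40, 18, 10, 7, 5, 4, 3, 2, 2, 1, 1], dtype=float)
spec = SpectrumUnfolded(12, counts)

print(f"total segregating sites     : {spec.total:.0f}")
print(f"rare fraction (unfolded)    : {fraction_rare(spec):.3f}")
print(f"rare fraction (folded)      : {fraction_rare(fold(spec)):.3f}")

# expected spectrum after subsampling to 6 chromosomes; some sites are lost
# (no derived copies drawn) or fixed in the subsample
proj = project(spec, 6)
masses = projection_masses(spec, 6)
print(f"projected to n=6            : {np.round(proj.counts, 2)}")
print(f"  expected lost / fixed     : {masses['lost']:.2f} / {masses['fixed']:.2f}")
print(f"  rare fraction at n=6      : {fraction_rare(proj):.3f}")
# rare fractions rise in small samples: only low-frequency variants that
# survive subsampling register, and they mostly appear as singletons
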