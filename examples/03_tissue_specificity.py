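"""Score tissue specificity of exonic parts with the tau index.

tau is 0 for uniformly expressed features and 1 for single-tissue ones.
"""

import pandas as pd

from aseview import tau_specificity
from aseview.gene_model import MetaExon
from aseview.specificity import exon_specificity_table

print("uniform (5,5,5,5):     tau =", tau_specificity([5, 5, 5, 5]))
print("one-hot (0,0,9,0):     tau =", tau_specificity([0, 0, 9, 0]))
print("graded  (8,4,0,0):     tau =", round(tau_specificity([8, 4, 0, 0]), 4))

metas = [MetaExon("chr1", 0, 100), MetaExon("chr1", 200, 300)]
matrix = pd.DataFrame(
    {"chr1:0-100": [9.0, 0.5, 0.2], "chr1:200-300": [3.0, 3.1, 2.9]},
    index=["brain", "heart", "liver"],
)
for s in exon_specificity_table(matrix, metas):
    print(f"{s.feature_id}: tau = {s.score:.3f}")
# The first exonic part is almost brain-exclusive (tau near 1); the
# second is expressed everywhere (tau near 0).
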