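"""Pairwise LD over the panel and detection of a conserved haplotype block.

Builds a cohort with a planted high-LD core (markers inherited together,
little historical recombination) flanked by independent markers — the
structure seen around SOD1, where a conserved block covers intron 1 through
the gene's end while exon 1 (with the p.A5V site) falls outside it.
"""

import numpy as np

import founderhap as fh
from founderhap.model import Marker, MarkerPanel

rng = np.random.default_rng(7)
n = 400
core = rng.integers(0, 2, n)
columns = [rng.integers(0, 2, n), rng.integers(0, 2, n)]   # independent flank
columns += [core] * 10                                     # 10-marker block
columns += [rng.integers(0, 2, n), rng.integers(0, 2, n)]  # independent flank
haps = [tuple("AC"[columns[m][i]] for m in range(14)) for i in range(n)]

panel = MarkerPanel(
    tuple(Marker(id=f"m{i:02d}", kind="snp", alleles=frozenset("AC")) for i in range(14))
)
matrix = fh.ld_matrix(haps, panel)
blocks = fh.detect_blocks(matrix, metric="dprime", threshold=0.90)

print("pairwise D' (rounded):")
print(matrix.dprime.round(2).to_string())
for b in blocks:
    print(
        f"\nblock: {b.marker_ids[0]}..{b.marker_ids[-1]} "
        f"({b.n_markers} markers, all pairs D' >= {b.threshold})"
    )
print("\nThe detected block is exactly the planted 10-marker core; the four "
      "flanking markers (like SOD1 exon 1) stay outside it.")
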