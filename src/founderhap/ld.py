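"""Pairwise linkage disequilibrium and haplotype-block detection.

Standard two-locus statistics from phased haplotypes: with major-allele
frequencies p_A, p_B and joint major-major frequency p_AB,

    D   = p_AB - p_A * p_B
    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B))
    D'  = |D| / D_max,   D_max = min(p_A (1-p_B), (1-p_A) p_B)   if D > 0
                         D_max = min(p_A p_B, (1-p_A) (1-p_B))   if D < 0

The sign of D depends on allele labelling, so only r^2 and D' are reported
by default.  Blocks are maximal contiguous runs of markers in which every
within-run pair meets a threshold on the chosen metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import LDError
from .model import Haplotype, MarkerPanel, allele_sort_key


def _column(haps, i):
    out = []
    for h in haps:
        a = h.alleles[i] if isinstance(h, Haplotype) else h[i]
        out.append(a)
    return out


def _major_allele(values):
    """Major allele (frequency >= 0.5; ties broken lexicographically)."""
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], allele_sort_key(kv[0])))
    return ordered[0][0], counts


def pairwise_ld(
    haps: Sequence,
    i: int,
    j: int,
    strict: bool = False,
) -> dict:
    """D, D' and r^2 between markers ``i`` and ``j`` of a phased haplotype set.

    Both markers must be biallelic in the sample and free of MISSING values
    (filter with complete-case selection first).  A monomorphic marker gives
    D = r^2 = D' = 0 by convention unless ``strict`` is set.
    """
    col_i, col_j = _column(haps, i), _column(haps, j)
    if not col_i:
        raise LDError("no haplotypes")
    for col, name in ((col_i, i), (col_j, j)):
        if any(a is None for a in col):
            raise LDError(f"MISSING allele at marker index {name}; drop first")
        if len(set(col)) > 2:
            raise LDError(f"marker index {name} is not biallelic in this sample")
    a_major, a_counts = _major_allele(col_i)
    b_major, b_counts = _major_allele(col_j)
    n = len(col_i)
    p_a = a_counts[a_major] / n
    p_b = b_counts[b_major] / n
    if len(a_counts) < 2 or len(b_counts) < 2:
        if strict:
            raise LDError("monomorphic marker in strict mode")
        return {"D": 0.0, "Dprime": 0.0, "r2": 0.0, "p_A": p_a, "p_B": p_b}
    p_ab = sum(1 for x, y in zip(col_i, col_j) if x == a_major and y == b_major) / n
    D = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = D * D / denom
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(D) / d_max if d_max > 0 else 0.0
    return {"D": D, "Dprime": dprime, "r2": r2, "p_A": p_a, "p_B": p_b}


@dataclass(frozen=True)
class LDMatrix:
    marker_ids: tuple
    r2: pd.DataFrame
    dprime: pd.DataFrame
    d_raw: pd.DataFrame
    p_major: pd.Series
    monomorphic: tuple = ()

    def __len__(self) -> int:
        return len(self.marker_ids)

    def metric(self, name: str) -> pd.DataFrame:
        if name not in ("r2", "dprime"):
            raise ValueError(f"unknown LD metric {name!r}")
        return self.r2 if name == "r2" else self.dprime

    def to_tsv(self, path: Union[str, Path], metric: str = "r2") -> None:
        self.metric(metric).to_csv(path, sep="\t", index_label="marker")


def ld_matrix(
    haps: Sequence,
    panel: MarkerPanel,
    marker_ids: Optional[Sequence[str]] = None,
) -> LDMatrix:
    """All-pairs LD over the panel's biallelic markers.

    Microsatellites are excluded; monomorphic markers are flagged and given
    zero rows/columns by convention.  Haplotypes MISSING at either marker of
    a pair are dropped for that pair (complete cases per pair).
    """
    if marker_ids is None:
        marker_ids = [m.id for m in panel if m.kind == "snp"]
    idx = [panel.index_of(mid) for mid in marker_ids]
    if len(idx) < 2:
        raise LDError("need at least 2 usable markers for an LD matrix")
    k = len(idx)
    r2 = np.eye(k)
    dp = np.eye(k)
    d = np.zeros((k, k))
    mono = []
    p_major = {}
    for a_pos, i in enumerate(idx):
        col = [x for x in _column(haps, i) if x is not None]
        if not col:
            raise LDError(f"marker {marker_ids[a_pos]} has no observed alleles")
        major, counts = _major_allele(col)
        p_major[marker_ids[a_pos]] = counts[major] / len(col)
        if len(counts) < 2:
            mono.append(marker_ids[a_pos])
            r2[a_pos, a_pos] = 0.0
            dp[a_pos, a_pos] = 0.0
    n_usable = 0
    for a_pos in range(k):
        for b_pos in range(a_pos + 1, k):
            i, j = idx[a_pos], idx[b_pos]
            pairs = [
                h
                for h in haps
                if (h.alleles if isinstance(h, Haplotype) else h)[i] is not None
                and (h.alleles if isinstance(h, Haplotype) else h)[j] is not None
            ]
            if not pairs:
                raise LDError(
                    f"no complete cases for pair {marker_ids[a_pos]},{marker_ids[b_pos]}"
                )
            stats = pairwise_ld(pairs, i, j)
            r2[a_pos, b_pos] = r2[b_pos, a_pos] = stats["r2"]
            dp[a_pos, b_pos] = dp[b_pos, a_pos] = stats["Dprime"]
            d[a_pos, b_pos] = d[b_pos, a_pos] = stats["D"]
            n_usable += 1
    polymorphic = k - len(mono)
    if polymorphic < 2:
        raise LDError("fewer than 2 polymorphic markers")
    ids = tuple(marker_ids)
    return LDMatrix(
        marker_ids=ids,
        r2=pd.DataFrame(r2, index=ids, columns=ids),
        dprime=pd.DataFrame(dp, index=ids, columns=ids),
        d_raw=pd.DataFrame(d, index=ids, columns=ids),
        p_major=pd.Series(p_major),
        monomorphic=tuple(mono),
    )


@dataclass(frozen=True)
class LDBlock:
    start: int  # marker index within the LD matrix, inclusive
    end: int  # inclusive
    metric: str
    threshold: float
    marker_ids: tuple

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1


def detect_blocks(
    m: LDMatrix,
    metric: str = "dprime",
    threshold: float = 0.90,
) -> list:
    """Greedy leftmost-maximal contiguous high-LD blocks.

    Scans left to right; a block is extended while EVERY within-block pair
    meets ``metric >= threshold``, and closed at the first marker that
    breaks the all-pairs condition.  Blocks have >=2 markers, are disjoint
    and ordered by start index.  Monomorphic markers never join a block.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    mat = m.metric(metric).to_numpy()
    k = len(m.marker_ids)
    usable = [mid not in m.monomorphic for mid in m.marker_ids]
    blocks = []
    start = 0
    while start < k - 1:
        if not usable[start]:
            start += 1
            continue
        end = start
        for nxt in range(start + 1, k):
            if not usable[nxt]:
                break
            if all(mat[prev, nxt] >= threshold for prev in range(start, nxt)):
                end = nxt
            else:
                break
        if end > start:
            blocks.append(
                LDBlock(
                    start=start,
                    end=end,
                    metric=metric,
                    threshold=threshold,
                    marker_ids=m.marker_ids[start : end + 1],
                )
            )
            start = end + 1
        else:
            start += 1
    return blocks


def blocks_to_frame(blocks: Sequence[LDBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_id": [b.marker_ids[0] for b in blocks],
            "end_id": [b.marker_ids[-1] for b in blocks],
            "n_markers": [b.n_markers for b in blocks],
            "metric": [b.metric for b in blocks],
            "threshold": [b.threshold for b in blocks],
        }
    )
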