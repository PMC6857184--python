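"""Founder-haplotype classification and mismatch accounting.

Implements the comparison logic of the published founder table: which
reference haplotypes a patient's genotypes are compatible with, and how many
sites two founder backgrounds differ at, skipping untyped sites and treating
published unresolved-phase entries (``C/G``) as ambiguous sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import FileFormatError, PanelMismatchError
from .model import (
    MISSING,
    Haplotype,
    MarkerPanel,
    SampleGenotypes,
    allele_to_str,
    genotype_to_str,
    is_ambiguous,
    parse_allele_token,
)
from .population import HaplotypeSpectrum


@dataclass(frozen=True)
class CompatibilityEntry:
    rank_name: str
    reference: Haplotype
    compatible: bool
    complement: Optional[Haplotype]  # leftover alleles if compatible


@dataclass(frozen=True)
class CompatibilityResult:
    entries: tuple

    @property
    def n_compatible(self) -> int:
        return sum(e.compatible for e in self.entries)

    def compatible_entries(self) -> tuple:
        return tuple(e for e in self.entries if e.compatible)


def _alleles_match(a, b, policy: str) -> bool:
    """Match two allele values under a missing/ambiguous policy.

    MISSING matches anything.  Ambiguous sets match when they intersect the
    other value ("lenient") or never ("strict").
    """
    if a is MISSING or b is MISSING:
        return True
    a_set = a if is_ambiguous(a) else frozenset([a])
    b_set = b if is_ambiguous(b) else frozenset([b])
    if is_ambiguous(a) or is_ambiguous(b):
        if policy == "strict":
            return False
        return bool(a_set & b_set)
    return a == b


def mismatch(
    a: Haplotype,
    b: Haplotype,
    policy: str = "lenient",
    exclude_indices: Sequence[int] = (),
) -> dict:
    """Count mismatching sites between two haplotypes on the same panel.

    Sites MISSING in either haplotype are skipped; ambiguous alleles match
    iff the sets intersect (``policy="lenient"``, default) or never
    (``"strict"``).  Returns ``n_mismatch``, ``n_compared`` and ``n_skipped``
    (skipped = missing-skipped + excluded, so compared + skipped = length).
    """
    if len(a) != len(b):
        raise PanelMismatchError("haplotypes have different panel lengths")
    if policy not in ("lenient", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    excluded = set(exclude_indices)
    n_mismatch = n_compared = 0
    for i, (x, y) in enumerate(zip(a.alleles, b.alleles)):
        if i in excluded or x is MISSING or y is MISSING:
            continue
        n_compared += 1
        if not _alleles_match(x, y, policy):
            n_mismatch += 1
    if n_compared == 0:
        raise PanelMismatchError("zero comparable sites between haplotypes")
    return {
        "n_mismatch": n_mismatch,
        "n_compared": n_compared,
        "n_skipped": len(a) - n_compared,
    }


def compatible_references(
    sg: SampleGenotypes,
    spectrum: HaplotypeSpectrum,
    mutation_marker: Optional[str] = None,
    mutant_allele=None,
    carrier_background: Optional[Haplotype] = None,
) -> CompatibilityResult:
    """Which spectrum haplotypes the sample's genotypes are compatible with.

    A reference ``h`` is compatible when at every marker one genotype allele
    equals ``h``'s allele (MISSING matches anything); the complement is the
    leftover allele vector.  With a mutation constraint the carrier
    background (typically absent from the reference panel, which lacks the
    mutation) must additionally equal ``h`` at all co-observed sites.
    """
    if spectrum.panel is not None and len(sg) != len(spectrum.panel):
        raise PanelMismatchError(
            "sample genotypes are not aligned to the spectrum panel"
        )
    ref_len = len(spectrum.entries[0].haplotype)
    if len(sg) != ref_len:
        raise PanelMismatchError(
            "sample genotypes are not aligned to the spectrum haplotypes"
        )
    constrained = mutation_marker is not None
    if constrained and carrier_background is None:
        raise ValueError("mutation constraint requires a carrier background")
    if carrier_background is not None and len(carrier_background) != ref_len:
        raise PanelMismatchError(
            "carrier background is not aligned to the spectrum panel"
        )
    entries = []
    for e in spectrum:
        ok = True
        leftover = []
        for (g1, g2), ref in zip(sg.genotypes, e.haplotype.alleles):
            if g1 is MISSING and g2 is MISSING:
                leftover.append(MISSING)
                continue
            if g1 == ref:
                leftover.append(g2)
            elif g2 == ref:
                leftover.append(g1)
            elif g1 is MISSING or g2 is MISSING:
                leftover.append(g1 if g2 is MISSING else g2)
            else:
                ok = False
                break
        if ok and constrained:
            mm = mismatch(carrier_background, e.haplotype)
            ok = mm["n_mismatch"] == 0
        entries.append(
            CompatibilityEntry(
                rank_name=e.rank_name,
                reference=e.haplotype,
                compatible=ok,
                complement=Haplotype(tuple(leftover)) if ok else None,
            )
        )
    return CompatibilityResult(entries=tuple(entries))


@dataclass(frozen=True)
class FounderComparison:
    """Founder-table-style allele matrix plus pairwise mismatch counts."""

    panel: MarkerPanel
    named: Mapping[str, Haplotype]
    samples: tuple  # SampleGenotypes
    alleles_frame: pd.DataFrame
    mismatch_frame: pd.DataFrame

    def to_tsv(self, path: Union[str, Path], include_samples: bool = True) -> None:
        frame = self.alleles_frame
        if not include_samples:
            frame = frame[[c for c in frame.columns if c in self.named]]
        frame.to_csv(path, sep="\t", index=True, index_label="marker")


def founder_table(
    named: Mapping[str, Haplotype],
    samples: Sequence[SampleGenotypes] = (),
    panel: Optional[MarkerPanel] = None,
    policy: str = "lenient",
) -> FounderComparison:
    """Render the founder-comparison matrix and pairwise mismatch counts.

    ``named`` maps labels (USA, SWE, CHN, IBS, ...) to haplotypes on one
    panel; ``samples`` adds patient genotype columns.  Mismatches are counted
    over co-observed sites only (see :func:`mismatch`).
    """
    if panel is None:
        raise ValueError("founder_table requires the marker panel")
    for label, h in named.items():
        if len(h) != len(panel):
            raise PanelMismatchError(f"haplotype {label!r} not aligned to panel")
    for sg in samples:
        if len(sg) != len(panel):
            raise PanelMismatchError(f"sample {sg.sample_id!r} not aligned to panel")
    data = {}
    for label, h in named.items():
        # untyped founder sites render as "-", the published-table convention
        data[label] = [
            "-" if a is MISSING else allele_to_str(a) for a in h.alleles
        ]
    for sg in samples:
        data[sg.sample_id] = [genotype_to_str(g) for g in sg.genotypes]
    alleles_frame = pd.DataFrame(data, index=list(panel.ids))
    labels = list(named)
    mm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            n = mismatch(named[la], named[lb], policy=policy)["n_mismatch"]
            mm.loc[la, lb] = mm.loc[lb, la] = n
    return FounderComparison(
        panel=panel,
        named=dict(named),
        samples=tuple(samples),
        alleles_frame=alleles_frame,
        mismatch_frame=mm,
    )


def parse_founder_table(
    path: Union[str, Path], panel: MarkerPanel
) -> dict:
    """Read a named-founder TSV (column ``marker`` + one column per label).

    Returns label -> :class:`Haplotype` aligned to ``panel`` (markers of the
    file must be a subset of the panel; panel markers absent from the file
    are MISSING).
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"founder table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    for mid in df[first]:
        if mid not in panel:
            raise FileFormatError(f"founder table marker {mid!r} not in panel")
    by_marker = df.set_index(first)
    named = {}
    for label in df.columns[1:]:
        alleles = []
        for m in panel:
            if m.id in by_marker.index:
                tok = by_marker.loc[m.id, label]
                alleles.append(
                    parse_allele_token(
                        "" if pd.isna(tok) else str(tok), m.kind, context=f"({label})"
                    )
                )
            else:
                alleles.append(MISSING)
        named[label] = Haplotype(tuple(alleles), label=label)
    return named


def default_founders(panel: Optional[MarkerPanel] = None) -> dict:
    """The packaged published founder haplotypes (USA, SWE, CHN, IBS)."""
    from .model import default_panel

    panel = panel or default_panel()
    with resources.as_file(
        resources.files("founderhap.data") / "sod1_founders_table1.tsv"
    ) as p:
        return parse_founder_table(p, panel)
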