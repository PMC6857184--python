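"""Phased reference panels and haplotype spectra.

Reads a phased VCF (e.g. a 1000 Genomes phase-3 chromosome-21 slice) plus a
sample->population map, extracts the two haplotypes of each sample over a
marker panel, and summarises them as a frequency-ranked haplotype spectrum.
Haplotypes are named "1", "2", ... by descending population frequency, the
convention used for the SOD1 region (the mutation-bearing variant of a named
background gets a "V" suffix, its wild-type counterpart an "A").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import FileFormatError
from .model import (
    Haplotype,
    MarkerPanel,
    allele_sort_key,
    allele_to_str,
)

logger = logging.getLogger(__name__)

#: 1000 Genomes phase-3 super-population groupings.  "GWC" is how the source
#: study spells the Gambian cohort; the 1KG code is GWD (mapped on input with
#: a warning).
SUPERPOPULATIONS = {
    "African": ("ACB", "ASW", "ESN", "GWD", "LWK", "MSL", "YRI"),
    "European": ("CEU", "FIN", "GBR", "IBS", "TSI"),
    "East Asian": ("CHB", "CHS", "CDX", "JPT", "KHV"),
    "South Asian": ("GIH", "PJL", "BEB", "STU", "ITU"),
    "Mixed American": ("CLM", "MXL", "PEL", "PUR"),
}

_CODE_ALIASES = {"GWC": "GWD"}


@dataclass(frozen=True)
class PanelSample:
    sample_id: str
    population: str
    super_population: str


@dataclass(frozen=True)
class PopulationPanel:
    """Phased haplotypes of a reference cohort over an effective panel."""

    panel: MarkerPanel
    samples: tuple  # PanelSample, VCF order
    haplotypes: tuple  # per sample: (Haplotype, Haplotype)
    dropped_markers: tuple = ()

    def __post_init__(self):
        for pair in self.haplotypes:
            if len(pair) != 2:
                raise FileFormatError("every sample contributes exactly 2 haplotypes")
            for h in pair:
                if len(h) != len(self.panel):
                    raise FileFormatError("haplotype length != effective panel length")

    @property
    def populations(self) -> tuple:
        return tuple(sorted({s.population for s in self.samples}))

    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SpectrumEntry:
    haplotype: Haplotype
    count: int
    frequency: Fraction
    rank_name: str


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Distinct haplotypes with counts, exact frequencies and rank names."""

    panel: Optional[MarkerPanel]
    entries: tuple
    total_haplotypes: int
    population_label: str = ""

    def __post_init__(self):
        if sum(e.count for e in self.entries) != self.total_haplotypes:
            raise ValueError("spectrum counts do not sum to total")
        if sum(e.frequency for e in self.entries) != 1:
            raise ValueError("spectrum frequencies do not sum to 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def haplotype_of_rank(self, rank: int) -> Haplotype:
        return self.entries[rank - 1].haplotype

    def rank_of(self, hap: Union[Haplotype, tuple]) -> Optional[int]:
        alleles = hap.alleles if isinstance(hap, Haplotype) else tuple(hap)
        for i, e in enumerate(self.entries, start=1):
            if e.haplotype.alleles == alleles:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank_name": [e.rank_name for e in self.entries],
                "haplotype": [e.haplotype.to_str() for e in self.entries],
                "count": [e.count for e in self.entries],
                "frequency": [round(float(e.frequency), 3) for e in self.entries],
            }
        )

    def to_json_obj(self) -> dict:
        return {
            "population": self.population_label,
            "total_haplotypes": self.total_haplotypes,
            "entries": [
                {
                    "rank_name": e.rank_name,
                    "haplotype": e.haplotype.to_str(),
                    "count": e.count,
                    "frequency": round(float(e.frequency), 6),
                }
                for e in self.entries
            ],
        }


def read_popmap(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample->population->super-population TSV."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"population map not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "population", "super_population"}
    if not required.issubset(df.columns):
        raise FileFormatError(
            f"population map {path} must have columns {sorted(required)}"
        )
    aliased = df["population"].isin(_CODE_ALIASES)
    if aliased.any():
        for code in sorted(set(df.loc[aliased, "population"])):
            logger.warning(
                "population code %s mapped to 1000 Genomes code %s",
                code,
                _CODE_ALIASES[code],
            )
        df.loc[aliased, "population"] = df.loc[aliased, "population"].map(
            _CODE_ALIASES
        )
    return df


def _vcf_allele(marker, seq: str):
    """Translate a VCF REF/ALT string into a panel allele."""
    if marker.kind == "snp":
        return seq.upper()
    # microsatellite: literal CA-sequence; allele = repeat count
    if len(seq) % 2 or set(seq.upper()) - {"C", "A"}:
        raise FileFormatError(
            f"cannot interpret {seq!r} as CA-repeat allele for {marker.id}"
        )
    return len(seq) // 2


def read_phased_vcf(
    vcf_path: Union[str, Path],
    panel: MarkerPanel,
    popmap_path: Union[str, Path],
) -> PopulationPanel:
    """Extract 2 phased haplotypes per sample over ``panel`` from a VCF.

    Markers are matched by ID, falling back to chrom+pos; panel markers not
    found in the VCF are dropped panel-wide and recorded in
    ``dropped_markers`` (this mirrors moving from the 16 assay markers to the
    14 SNPs present in the reference data).  Unphased genotypes are an error.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileFormatError(f"VCF not found: {vcf_path}")
    popmap = read_popmap(popmap_path)
    pop_by_sample = {
        r["sample"]: (r["population"], r["super_population"])
        for _, r in popmap.iterrows()
    }

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    missing = [s for s in sample_ids if s not in pop_by_sample]
    if missing:
        raise FileFormatError(
            f"sample(s) missing from population map: {missing[:5]}"
        )

    by_id = {m.id: m for m in panel}
    by_pos = {(m.chrom, m.pos): m for m in panel if m.pos is not None}
    found: dict = {}
    for variant in vcf:
        marker = None
        if variant.ID and variant.ID in by_id:
            marker = by_id[variant.ID]
        elif (variant.CHROM.lstrip("chr"), variant.POS) in by_pos:
            marker = by_pos[(variant.CHROM.lstrip("chr"), variant.POS)]
        if marker is None or marker.id in found:
            continue
        alleles = [_vcf_allele(marker, a) for a in [variant.REF] + variant.ALT]
        columns = []
        for si, g in enumerate(variant.genotypes):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                raise FileFormatError(
                    f"missing genotype for sample {sample_ids[si]} at {marker.id}"
                )
            if not phased:
                raise FileFormatError(
                    f"unphased genotype for sample {sample_ids[si]} at {marker.id}"
                )
            columns.append((alleles[a0], alleles[a1]))
        found[marker.id] = columns

    if not found:
        raise FileFormatError("zero panel markers found in VCF")
    kept = [m for m in panel if m.id in found]
    dropped = tuple(m.id for m in panel if m.id not in found)
    eff_panel = MarkerPanel(tuple(kept), name=f"{panel.name}.effective")

    samples = tuple(
        PanelSample(s, *pop_by_sample[s]) for s in sample_ids
    )
    haplotypes = []
    for si in range(len(sample_ids)):
        hap_a = tuple(found[m.id][si][0] for m in kept)
        hap_b = tuple(found[m.id][si][1] for m in kept)
        haplotypes.append((Haplotype(hap_a), Haplotype(hap_b)))
    return PopulationPanel(
        panel=eff_panel,
        samples=samples,
        haplotypes=tuple(haplotypes),
        dropped_markers=dropped,
    )


def extract_haplotypes(
    pp: PopulationPanel,
    populations: Optional[Iterable[str]] = None,
    super_population: Optional[str] = None,
) -> list:
    """Haplotypes of the selected samples, 2 per sample, deterministic order.

    Select by population codes, by super-population name (resolved through
    :data:`SUPERPOPULATIONS`), or neither for all samples.
    """
    if populations is not None and super_population is not None:
        raise ValueError("give either populations or super_population, not both")
    if super_population is not None:
        if super_population not in SUPERPOPULATIONS:
            raise KeyError(
                f"unknown super-population {super_population!r}; "
                f"valid: {sorted(SUPERPOPULATIONS)}"
            )
        codes = set(SUPERPOPULATIONS[super_population])
    elif populations is not None:
        codes = {_CODE_ALIASES.get(c, c) for c in populations}
        if not codes:
            raise ValueError("empty population selector")
        valid = set(s.population for s in pp.samples)
        unknown = codes - valid
        if unknown:
            raise KeyError(
                f"unknown population code(s) {sorted(unknown)}; valid: {sorted(valid)}"
            )
    else:
        codes = None
    out = []
    for sample, pair in zip(pp.samples, pp.haplotypes):
        if codes is None or sample.population in codes:
            out.extend(pair)
    return out


def build_spectrum(
    haps: Sequence[Union[Haplotype, tuple]],
    label: str = "",
    panel: Optional[MarkerPanel] = None,
) -> HaplotypeSpectrum:
    """Count distinct haplotypes and name them by descending frequency.

    Frequencies are exact rationals; ties in count are broken by the
    lexicographic order of the allele string so output is deterministic.
    """
    if not haps:
        raise ValueError("cannot build a spectrum from zero haplotypes")
    vectors = [h.alleles if isinstance(h, Haplotype) else tuple(h) for h in haps]
    length = len(vectors[0])
    for v in vectors:
        if len(v) != length:
            raise ValueError("mixed haplotype lengths")
        for a in v:
            if a is None or isinstance(a, frozenset):
                raise ValueError(
                    "spectrum haplotypes must be fully observed and unambiguous"
                )
    counts: dict = {}
    for v in vectors:
        counts[v] = counts.get(v, 0) + 1
    total = len(vectors)
    ordered = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], tuple(allele_sort_key(a) for a in kv[0])),
    )
    entries = tuple(
        SpectrumEntry(
            haplotype=Haplotype(v, label=str(rank)),
            count=c,
            frequency=Fraction(c, total),
            rank_name=str(rank),
        )
        for rank, (v, c) in enumerate(ordered, start=1)
    )
    return HaplotypeSpectrum(
        panel=panel, entries=entries, total_haplotypes=total, population_label=label
    )


@dataclass(frozen=True)
class CrossPopulationTable:
    """Per-group haplotype counts/frequencies plus a pooled "all" column."""

    haplotypes: tuple  # allele tuples, sorted by pooled frequency desc
    groups: tuple  # group names in input order, then "all"
    frame: pd.DataFrame = field(compare=False)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def cross_population_table(
    pp: PopulationPanel,
    groupings: Mapping[str, Sequence[str]],
) -> CrossPopulationTable:
    """Haplotype frequencies per group of population codes, plus pooled.

    One row per haplotype observed in any group; rows sorted by pooled
    frequency descending (ties lexicographic).
    """
    if not groupings:
        raise ValueError("empty grouping")
    group_haps = {}
    for name, codes in groupings.items():
        if not codes:
            raise ValueError(f"group {name!r} has no population codes")
        group_haps[name] = [
            h.alleles for h in extract_haplotypes(pp, populations=codes)
        ]
    pooled = [v for haps in group_haps.values() for v in haps]
    if not pooled:
        raise ValueError("groupings select zero samples")
    pooled_spec = build_spectrum(pooled, label="all", panel=pp.panel)
    rows = []
    for e in pooled_spec:
        row = {
            "haplotype": e.haplotype.to_str(),
            ("all", "count"): e.count,
            ("all", "frequency"): round(float(e.frequency), 3),
        }
        for name, haps in group_haps.items():
            c = sum(1 for v in haps if v == e.haplotype.alleles)
            row[(name, "count")] = c
            row[(name, "frequency")] = round(c / len(haps), 3) if haps else 0.0
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("haplotype")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    order = [g for g in groupings] + ["all"]
    frame = frame[[(g, f) for g in order for f in ("count", "frequency")]]
    return CrossPopulationTable(
        haplotypes=tuple(e.haplotype.alleles for e in pooled_spec),
        groups=tuple(order),
        frame=frame,
    )


def label_family_haplotypes(
    haps: Sequence[Haplotype],
    spectrum: HaplotypeSpectrum,
    family_panel: MarkerPanel,
    mutation_marker: str,
    mutant_allele,
) -> dict:
    """Rank-style labels for family haplotypes against a reference spectrum.

    Each family haplotype (over the full assay panel) is projected onto the
    spectrum's panel and labelled by its frequency rank.  When several family
    haplotypes share a rank, the mutation-bearing one is suffixed "V", its
    wild-type counterpart "A", and further duplicates get "*" — producing the
    1A / 1V / 4 / 1A* style of family-figure annotation.
    """
    if spectrum.panel is None:
        raise ValueError("spectrum must carry its panel for labelling")
    mut_idx = family_panel.index_of(mutation_marker)
    src_idx = [family_panel.index_of(mid) for mid in spectrum.panel.ids]
    ranked: list = []
    for h in haps:
        projected = tuple(h.alleles[i] for i in src_idx)
        rank = spectrum.rank_of(projected)
        ranked.append((h, rank, h.alleles[mut_idx] == mutant_allele))
    rank_counts: dict = {}
    for _, rank, _ in ranked:
        rank_counts[rank] = rank_counts.get(rank, 0) + 1
    labels: dict = {}
    seen: dict = {}
    for h, rank, has_mut in ranked:
        base = "?" if rank is None else str(rank)
        if rank_counts[rank] > 1:
            base += "V" if has_mut else "A"
        elif has_mut:
            base += "V"
        n_prev = seen.get(base, 0)
        seen[base] = n_prev + 1
        labels[h] = base + "*" * n_prev
    return labels


def write_spectrum_tsv(spectrum: HaplotypeSpectrum, path: Union[str, Path]) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def write_cross_population_tsv(
    table: CrossPopulationTable, path: Union[str, Path]
) -> None:
    flat = table.frame.copy()
    flat.columns = [f"{g}_{f}" for g, f in flat.columns]
    flat.to_csv(path, sep="\t")
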