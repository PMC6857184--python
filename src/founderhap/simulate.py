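"""Synthetic study-condition generator.

Produces everything the pipeline consumes without any downloads: phased
reference cohorts drawn i.i.d. from specified per-population haplotype
spectra, nuclear families with a rare mutation implanted on a chosen
background haplotype of one parental lineage, and phase-stripped genotypes.

The defaults emulate the study conditions: an Iberian-like reference
spectrum of 8 haplotypes over the 14-SNP population panel (frequencies are
stand-in values, the published figure prints bars, not numbers), a reference
cohort of 102 diploid samples, and a family of two ungenotyped parents and
four genotyped offspring of whom exactly two inherited the mutant paternal
haplotype.  A worldwide configuration adds four more super-population
spectra over a 21-haplotype pool whose generating frequencies for the
European- and American-founder backgrounds are the published population
frequencies (EUR 0.298/0.062, EAS 0.306/0.385, AFR 0.037/0.045).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import FounderhapError
from .model import (
    MISSING,
    Haplotype,
    MarkerPanel,
    Individual,
    Pedigree,
    SampleGenotypes,
    MUTATION_MARKER,
    MUTANT_ALLELE,
    POP14_IDS,
    allele_to_str,
    default_panel,
    genotype_key,
    subset_panel,
    write_genotypes,
    write_panel,
    write_ped,
)
from .population import PanelSample, PopulationPanel

#: Stand-in Iberian-like spectrum frequencies (8 haplotypes, descending).
IBS_LIKE_FREQUENCIES = (0.45, 0.20, 0.12, 0.08, 0.06, 0.04, 0.03, 0.02)

#: 1000-Genomes-like cohort sizes per population code used by the worldwide
#: configuration (phase-3 scale).
WORLDWIDE_N = {
    "IBS": 102, "CEU": 99, "FIN": 99, "GBR": 91, "TSI": 107,
    "YRI": 108, "LWK": 99, "GWD": 113, "ACB": 96, "ASW": 61, "ESN": 99, "MSL": 85,
    "CHB": 103, "CHS": 105, "CDX": 93, "JPT": 104, "KHV": 99,
    "GIH": 103, "PJL": 96, "BEB": 86, "STU": 102, "ITU": 102,
    "CLM": 94, "MXL": 64, "PEL": 85, "PUR": 104,
}

WORLDWIDE_SUPERPOP = {
    **{c: "European" for c in ("IBS", "CEU", "FIN", "GBR", "TSI")},
    **{c: "African" for c in ("YRI", "LWK", "GWD", "ACB", "ASW", "ESN", "MSL")},
    **{c: "East Asian" for c in ("CHB", "CHS", "CDX", "JPT", "KHV")},
    **{c: "South Asian" for c in ("GIH", "PJL", "BEB", "STU", "ITU")},
    **{c: "Mixed American" for c in ("CLM", "MXL", "PEL", "PUR")},
}


@dataclass(frozen=True)
class FamilyConfig:
    """Nuclear-family layout; defaults mirror the studied pedigree."""

    n_offspring: int = 4
    father_carrier: bool = True
    background_rank: int = 1  # 1-based rank in the carrier population's spectrum
    father_genotyped: bool = False
    mother_genotyped: bool = False
    #: exact number of carrier offspring (None = free Mendelian segregation)
    n_carriers: Optional[int] = 2


@dataclass(frozen=True)
class SimConfig:
    """Full simulation scenario; ``seed`` determines every output."""

    panel: MarkerPanel
    spectra: Dict[str, List[Tuple[tuple, float]]]  # pop -> [(alleles, freq)]
    n_samples: Dict[str, int]
    superpop: Dict[str, str]
    seed: int
    family: FamilyConfig = field(default_factory=FamilyConfig)
    mutation: Tuple[str, str] = (MUTATION_MARKER, MUTANT_ALLELE)
    carrier_population: str = "IBS"
    #: marker ids present in the synthetic *reference* panel (the mutation
    #: site and the microsatellite are absent, as in real reference data)
    reference_ids: Tuple[str, ...] = POP14_IDS
    genotyping_error_rate: float = 0.0

    def __post_init__(self):
        for pop, spec in self.spectra.items():
            total = sum(f for _, f in spec)
            if abs(total - 1.0) > 1e-9:
                raise FounderhapError(
                    f"spectrum frequencies for {pop!r} sum to {total}, not 1"
                )
            vectors = [v for v, _ in spec]
            if len(set(vectors)) != len(vectors):
                raise FounderhapError(f"duplicate haplotypes in {pop!r} spectrum")
            for v in vectors:
                if len(v) != len(self.panel):
                    raise FounderhapError("spectrum haplotype length != panel length")
        if self.family.father_carrier:
            if self.mutation is None:
                raise FounderhapError("father_carrier requires a mutation spec")
            spec = self.spectra[self.carrier_population]
            if not (1 <= self.family.background_rank <= len(spec)):
                raise FounderhapError("background_rank outside the carrier spectrum")


def _flippable_sites(panel: MarkerPanel) -> list:
    """Biallelic non-mutation SNP indices, the sites synthetic spectra vary."""
    return [
        i
        for i, m in enumerate(panel)
        if m.kind == "snp" and len(m.alleles) == 2 and not m.is_mutation_site
    ]


def _flip(panel: MarkerPanel, alleles: tuple, i: int) -> tuple:
    pair = sorted(panel.markers[i].alleles, key=str)
    other = pair[1] if alleles[i] == pair[0] else pair[0]
    return alleles[:i] + (other,) + alleles[i + 1:]


def _base_haplotype(panel: MarkerPanel) -> tuple:
    """Wild-type Iberian-like background over the full assay panel."""
    from .classify import default_founders

    founders = default_founders(default_panel())
    ibs = founders["IBS"].alleles
    src = default_panel()
    out = []
    for m in panel:
        if m.id == "CA_repeat":
            out.append(12)
        elif m.is_mutation_site:
            out.append("C")  # wild type; the founder table row shows the mutant T
        else:
            out.append(ibs[src.index_of(m.id)])
    return tuple(out)


def haplotype_pool(panel: MarkerPanel, n: int) -> list:
    """``n`` distinct haplotypes over ``panel``, distinct after projection to
    the reference SNPs.

    Pool member 0 is the Iberian-like background; member 1 flips every
    biallelic site but the first (the American-founder-like background);
    further members flip deterministic site subsets.  Microsatellite repeat
    counts cycle over 10..13.
    """
    sites = _flippable_sites(panel)
    if n > 2 ** len(sites):
        raise FounderhapError(f"cannot build {n} distinct haplotypes")
    base = _base_haplotype(panel)
    ca_idx = next((i for i, m in enumerate(panel) if m.kind == "microsatellite"), None)
    usa_mask = sum(1 << k for k in range(1, len(sites)))  # all but first site
    masks = [0, usa_mask]
    mask = 1
    while len(masks) < n:
        if mask not in masks:
            masks.append(mask)
        mask += 1
    pool = []
    for rank, mask in enumerate(masks):
        h = base
        for k, i in enumerate(sites):
            if mask >> k & 1:
                h = _flip(panel, h, i)
        if ca_idx is not None:
            counts = sorted(panel.markers[ca_idx].alleles)
            h = h[:ca_idx] + (counts[rank % len(counts)],) + h[ca_idx + 1:]
        pool.append(h)
    return pool


def ibs_like_spectrum(panel: MarkerPanel) -> list:
    """The default 8-haplotype Iberian-like generating spectrum."""
    pool = haplotype_pool(panel, 8)
    return list(zip(pool, IBS_LIKE_FREQUENCIES))


def default_config(seed: int, panel: Optional[MarkerPanel] = None) -> SimConfig:
    """Single-population (IBS-like, n=102) scenario with the studied family."""
    panel = panel or default_panel()
    return SimConfig(
        panel=panel,
        spectra={"IBS": ibs_like_spectrum(panel)},
        n_samples={"IBS": 102},
        superpop={"IBS": "European"},
        seed=seed,
    )


#: index into the 21-haplotype pool -> generating frequency, per super-population.
#: Entries 0 and 1 are the European- and American-founder backgrounds; their
#: EUR/EAS/AFR frequencies are the published values.
WORLDWIDE_SPECTRA_SPEC = {
    "European": {0: 0.298, 1: 0.062, 2: 0.17, 3: 0.14, 4: 0.10, 5: 0.08,
                 6: 0.06, 7: 0.04, 8: 0.03, 9: 0.02},
    "East Asian": {1: 0.385, 0: 0.306, 10: 0.12, 11: 0.08, 12: 0.05,
                   13: 0.04, 14: 0.019},
    "African": {0: 0.037, 1: 0.045, 15: 0.30, 16: 0.25, 17: 0.17, 18: 0.10,
                2: 0.06, 10: 0.038},
    "South Asian": {0: 0.35, 1: 0.20, 10: 0.15, 19: 0.12, 11: 0.10, 4: 0.08},
    "Mixed American": {0: 0.32, 1: 0.28, 20: 0.14, 15: 0.10, 2: 0.09, 12: 0.07},
}


def worldwide_config(seed: int, panel: Optional[MarkerPanel] = None) -> SimConfig:
    """Five-super-population scenario over a 21-haplotype pool."""
    panel = panel or default_panel()
    pool = haplotype_pool(panel, 21)
    spectra = {}
    for pop, n in WORLDWIDE_N.items():
        sp = WORLDWIDE_SPECTRA_SPEC[WORLDWIDE_SUPERPOP[pop]]
        spectra[pop] = [(pool[i], f) for i, f in sp.items()]
    return SimConfig(
        panel=panel,
        spectra=spectra,
        n_samples=dict(WORLDWIDE_N),
        superpop=dict(WORLDWIDE_SUPERPOP),
        seed=seed,
    )


def emulate_study_config(seed: int) -> SimConfig:
    """The study-emulation preset: IBS-like cohort plus the Fig-1-like family
    (4 genotyped offspring, 2 carriers, deceased — hence ungenotyped —
    parents, mutation on the rank-1 background of the paternal lineage)."""
    return default_config(seed)


def _reference_panel(cfg: SimConfig) -> MarkerPanel:
    keep = [mid for mid in cfg.reference_ids if mid in cfg.panel]
    return subset_panel(cfg.panel, keep_ids=keep)


def sample_panel(cfg: SimConfig) -> tuple:
    """Draw a phased reference cohort; returns (PopulationPanel, truth).

    Each sample's two haplotypes are i.i.d. draws from its population's
    spectrum, projected onto the reference marker set (the mutation site and
    microsatellite are withheld, as in real reference panels).
    """
    if not cfg.n_samples or any(n <= 0 for n in cfg.n_samples.values()):
        raise FounderhapError("every population needs at least one sample")
    rng = np.random.default_rng([cfg.seed, 0])
    ref_panel = _reference_panel(cfg)
    keep_idx = [cfg.panel.index_of(mid) for mid in ref_panel.ids]
    samples = []
    haplotypes = []
    assignments = {}
    for pop in cfg.n_samples:
        spec = cfg.spectra[pop]
        freqs = np.array([f for _, f in spec], dtype=float)
        freqs = freqs / freqs.sum()
        n = cfg.n_samples[pop]
        draws = rng.choice(len(spec), size=(n, 2), p=freqs)
        for i in range(n):
            sid = f"{pop}_{i:04d}"
            samples.append(PanelSample(sid, pop, cfg.superpop[pop]))
            pair = []
            for j in range(2):
                full = spec[draws[i, j]][0]
                pair.append(Haplotype(tuple(full[k] for k in keep_idx)))
            haplotypes.append(tuple(pair))
            assignments[sid] = [int(draws[i, 0]) + 1, int(draws[i, 1]) + 1]
    pp = PopulationPanel(
        panel=ref_panel,
        samples=tuple(samples),
        haplotypes=tuple(haplotypes),
        dropped_markers=tuple(m for m in cfg.panel.ids if m not in ref_panel.ids),
    )
    truth = {
        "seed": cfg.seed,
        "assignments": assignments,
        "spectra": {
            pop: [
                {"haplotype": Haplotype(v).to_str(), "frequency": f}
                for v, f in cfg.spectra[pop]
            ]
            for pop in cfg.spectra
        },
    }
    return pp, truth


def _draw_hap(rng, spec) -> tuple:
    freqs = np.array([f for _, f in spec], dtype=float)
    freqs = freqs / freqs.sum()
    return spec[int(rng.choice(len(spec), p=freqs))][0]


def make_family(cfg: SimConfig) -> tuple:
    """Generate the nuclear family; returns (Pedigree, genotypes, truth).

    The mutant allele is implanted on the carrier parent's haplotype of the
    configured spectrum rank; offspring inherit one haplotype per parent
    without recombination; genotypes are returned phase-stripped.  When
    ``n_carriers`` is set, that many offspring (chosen uniformly) receive the
    mutant paternal haplotype and the rest receive the other one, mirroring
    the observed segregation.
    """
    fam = cfg.family
    if fam.father_carrier and cfg.mutation is None:
        raise FounderhapError("father_carrier set but mutation unset")
    rng = np.random.default_rng([cfg.seed, 1])
    panel = cfg.panel
    spec = cfg.spectra[cfg.carrier_population]
    mut_marker, mut_allele = cfg.mutation
    mut_idx = panel.index_of(mut_marker)

    if fam.father_carrier:
        background = spec[fam.background_rank - 1][0]
        mutant_hap = background[:mut_idx] + (mut_allele,) + background[mut_idx + 1:]
        father = (mutant_hap, _draw_hap(rng, spec))
    else:
        father = (_draw_hap(rng, spec), _draw_hap(rng, spec))
    mother = (_draw_hap(rng, spec), _draw_hap(rng, spec))

    n = fam.n_offspring
    maternal_bits = rng.integers(0, 2, size=n)
    if fam.father_carrier and fam.n_carriers is not None:
        if not (0 <= fam.n_carriers <= n):
            raise FounderhapError("n_carriers outside 0..n_offspring")
        carrier_idx = set(
            int(i) for i in rng.choice(n, size=fam.n_carriers, replace=False)
        )
        paternal_bits = [0 if i in carrier_idx else 1 for i in range(n)]
    else:
        paternal_bits = [int(b) for b in rng.integers(0, 2, size=n)]

    individuals = [
        Individual("I:1", sex=1, affected=2 if fam.father_carrier else 1),
        Individual("I:2", sex=2, affected=1),
    ]
    genotypes = []
    transmissions = {}
    carriers = []
    kid_ids = []
    for i in range(n):
        kid = f"II:{i + 1}"
        kid_ids.append(kid)
        bp, bm = paternal_bits[i], int(maternal_bits[i])
        transmissions[kid] = [bp, bm]
        pat, mat = father[bp], mother[bm]
        is_carrier = pat[mut_idx] == mut_allele or mat[mut_idx] == mut_allele
        if is_carrier:
            carriers.append(kid)
        individuals.append(
            Individual(
                kid,
                father="I:1",
                mother="I:2",
                sex=1 + i % 2,
                affected=2 if is_carrier else 1,
            )
        )
        genos = []
        for m in range(len(panel)):
            pair = [pat[m], mat[m]]
            if cfg.genotyping_error_rate > 0 and rng.random() < cfg.genotyping_error_rate:
                marker = panel.markers[m]
                others = sorted(set(marker.alleles) - {pair[0]}, key=str)
                if others:
                    pair[0] = others[int(rng.integers(0, len(others)))]
            genos.append(genotype_key(tuple(pair)))
        genotypes.append(SampleGenotypes(kid, tuple(genos)))
    if fam.father_genotyped:
        genotypes.insert(
            0,
            SampleGenotypes(
                "I:1",
                tuple(genotype_key((father[0][m], father[1][m])) for m in range(len(panel))),
            ),
        )
    if fam.mother_genotyped:
        genotypes.insert(
            0,
            SampleGenotypes(
                "I:2",
                tuple(genotype_key((mother[0][m], mother[1][m])) for m in range(len(panel))),
            ),
        )
    ped = Pedigree(tuple(individuals))
    truth = {
        "seed": cfg.seed,
        "father": [Haplotype(h).to_str() for h in father],
        "mother": [Haplotype(h).to_str() for h in mother],
        "transmissions": transmissions,
        "carriers": carriers,
        "background": Haplotype(father[0]).to_str() if fam.father_carrier else None,
        "background_rank": fam.background_rank if fam.father_carrier else None,
        "mutation": {"marker": mut_marker, "allele": allele_to_str(mut_allele)},
    }
    return ped, genotypes, truth


def _allele_to_vcf(marker, allele) -> str:
    if marker.kind == "snp":
        return str(allele)
    return "CA" * int(allele)


def write_vcf(pp: PopulationPanel, path: Union[str, Path], seed: Optional[int] = None) -> None:
    """Write a phased VCF for a (synthetic) population panel.

    Deterministic output: no timestamps; the seed goes into the header.
    Positions fall back to ``5000 + 1000*i`` when the panel has none.
    """
    lines = ["##fileformat=VCFv4.2", "##source=founderhap-simulate"]
    if seed is not None:
        lines.append(f"##founderhap_seed={seed}")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = sorted({m.chrom for m in pp.panel})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [s.sample_id for s in pp.samples]
    lines.append("\t".join(header))
    for i, marker in enumerate(pp.panel):
        observed = []
        for pair in pp.haplotypes:
            for h in pair:
                a = h.alleles[i]
                if a not in observed:
                    observed.append(a)
        alleles = sorted(observed, key=str)
        ref, alts = alleles[0], alleles[1:]
        if not alts:
            alts = ["."]
        index = {a: k for k, a in enumerate(alleles)}
        pos = marker.pos if marker.pos is not None else 5000 + 1000 * i
        row = [
            marker.chrom,
            str(pos),
            marker.id,
            _allele_to_vcf(marker, ref),
            ",".join(_allele_to_vcf(marker, a) for a in alts) if alts != ["."] else ".",
            ".",
            "PASS",
            ".",
            "GT",
        ]
        for pair in pp.haplotypes:
            row.append(f"{index[pair[0].alleles[i]]}|{index[pair[1].alleles[i]]}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_popmap(pp: PopulationPanel, path: Union[str, Path], seed: Optional[int] = None) -> None:
    lines = []
    if seed is not None:
        lines.append(f"# founderhap seed={seed}")
    lines.append("sample\tpopulation\tsuper_population")
    for s in pp.samples:
        lines.append(f"{s.sample_id}\t{s.population}\t{s.super_population}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_set(cfg: SimConfig, outdir: Union[str, Path]) -> dict:
    """Write the full fixture bundle; returns a name->path dict.

    Files: panel.tsv, reference.vcf, popmap.tsv, family.ped,
    family_genotypes.tsv, truth.json — all deterministic per seed and
    re-readable by the pipeline's own parsers.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise FounderhapError(f"cannot write to {outdir}: {exc}") from exc
    pp, panel_truth = sample_panel(cfg)
    ped, genos, family_truth = make_family(cfg)
    paths = {
        "panel": outdir / "panel.tsv",
        "vcf": outdir / "reference.vcf",
        "popmap": outdir / "popmap.tsv",
        "ped": outdir / "family.ped",
        "genotypes": outdir / "family_genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_panel(cfg.panel, paths["panel"])
    write_vcf(pp, paths["vcf"], seed=cfg.seed)
    write_popmap(pp, paths["popmap"], seed=cfg.seed)
    write_ped(ped, paths["ped"])
    write_genotypes(genos, cfg.panel, paths["genotypes"])
    truth = {"seed": cfg.seed, "panel": panel_truth, "family": family_truth}
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
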