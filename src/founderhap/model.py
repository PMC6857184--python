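"""Domain types: markers, panels, alleles, haplotypes, genotypes, pedigrees.

Alleles are plain Python values:

* SNP allele          -> single-character string (``"C"``)
* microsatellite      -> positive ``int`` repeat count (``12``)
* missing             -> ``None`` (exported as :data:`MISSING`)
* ambiguous           -> ``frozenset`` of >=2 observed alleles (unresolved
  phase in a published genotype, e.g. the Chinese case's ``C/G`` entries)

A :class:`Haplotype` is an allele vector aligned to a :class:`MarkerPanel`;
marker order is authoritative from the panel definition file (the order used
throughout the source family figure), not genomic position, because every
downstream computation is order-based over the fixed panel.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .errors import FileFormatError, PanelMismatchError

MISSING = None

#: Tokens accepted as "missing" in text inputs (the paper prints both "-"
#: and a unicode minus).
_MISSING_TOKENS = {".", "-", "−", "NA", ""}

_IUPAC = set("ACGTRYSWKMBDHVN")

Allele = Union[str, int, None, frozenset]

#: The mutation studied: SOD1 c.14C>T, p.A5V (legacy A4V).
MUTATION_MARKER = "rs121912442"
MUTANT_ALLELE = "T"

#: Population-analysis preset: the 15 SNPs of the founder table minus the
#: mutation site (absent from reference panels); the microsatellite is not a
#: SNP and is likewise excluded.  14 markers.
POP14_IDS = (
    "rs4817415", "rs2070422", "rs1008270", "rs9974610", "rs2173962",
    "rs202445", "rs4816405", "rs2070424", "rs1041740", "rs2833475",
    "rs16988427", "rs2833481", "rs2070423", "rs2833483",
)


def is_missing(a: Allele) -> bool:
    return a is None


def is_ambiguous(a: Allele) -> bool:
    return isinstance(a, frozenset)


def allele_to_str(a: Allele) -> str:
    if a is None:
        return "."
    if isinstance(a, frozenset):
        return "/".join(allele_to_str(x) for x in sorted(a, key=_allele_key))
    return str(a)


def _allele_key(a: Allele):
    """Deterministic sort key across ints, strings and missing."""
    if a is None:
        return (0, "")
    if isinstance(a, frozenset):
        return (3, tuple(sorted(_allele_key(x) for x in a)))
    if isinstance(a, int):
        return (1, f"{a:06d}")
    return (2, str(a))


def allele_sort_key(a: Allele):
    return _allele_key(a)


def parse_allele_token(token: str, kind: str, *, context: str = "") -> Allele:
    """Parse one allele token from a text file.

    ``kind`` is ``"snp"`` or ``"microsatellite"``; ``X/Y`` tokens become
    ambiguous sets (SNPs only).
    """
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING
    if "/" in token:
        parts = [parse_allele_token(p, kind, context=context) for p in token.split("/")]
        if any(p is None for p in parts) or len(set(parts)) < 2:
            raise FileFormatError(f"malformed ambiguous allele {token!r} {context}")
        return frozenset(parts)
    if kind == "snp":
        tok = token.upper()
        if len(tok) != 1 or tok not in _IUPAC:
            raise FileFormatError(f"malformed SNP allele {token!r} {context}")
        return tok
    if kind == "microsatellite":
        if not re.fullmatch(r"\d+", token) or int(token) <= 0:
            raise FileFormatError(
                f"malformed microsatellite repeat count {token!r} {context}"
            )
        return int(token)
    raise FileFormatError(f"unknown marker kind {kind!r} {context}")


@dataclass(frozen=True)
class Marker:
    """One panel marker: a SNP (rsID) or the CA microsatellite."""

    id: str
    kind: str  # "snp" | "microsatellite"
    chrom: str = "21"
    pos: Optional[int] = None  # 1-based GRCh37; optional metadata
    alleles: frozenset = frozenset()
    is_mutation_site: bool = False

    def __post_init__(self):
        if not self.id:
            raise FileFormatError("marker id must be nonempty")
        if self.kind not in ("snp", "microsatellite"):
            raise FileFormatError(f"unknown kind {self.kind!r} for marker {self.id}")
        for a in self.alleles:
            if self.kind == "snp" and not (isinstance(a, str) and a in _IUPAC):
                raise FileFormatError(f"bad SNP allele {a!r} for marker {self.id}")
            if self.kind == "microsatellite" and not (isinstance(a, int) and a > 0):
                raise FileFormatError(f"bad repeat count {a!r} for marker {self.id}")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel; order is fixed and meaningful."""

    markers: tuple
    name: str = "panel"

    def __post_init__(self):
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FileFormatError(f"duplicate marker id(s) in panel: {dup}")
        if sum(m.is_mutation_site for m in self.markers) > 1:
            raise FileFormatError("at most one mutation-site marker allowed")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    @property
    def ids(self) -> tuple:
        return tuple(m.id for m in self.markers)

    def index_of(self, marker_id: str) -> int:
        try:
            return self.ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in panel {self.name!r}") from None

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.ids

    def get(self, marker_id: str) -> Marker:
        return self.markers[self.index_of(marker_id)]

    @property
    def mutation_site(self) -> Optional[Marker]:
        for m in self.markers:
            if m.is_mutation_site:
                return m
        return None


@dataclass(frozen=True)
class Haplotype:
    """Allele vector aligned to a MarkerPanel; label is annotation only."""

    alleles: tuple
    label: Optional[str] = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.alleles)

    def __getitem__(self, i: int) -> Allele:
        return self.alleles[i]

    def is_complete(self) -> bool:
        return all(a is not None for a in self.alleles)

    def to_str(self) -> str:
        return "-".join(allele_to_str(a) for a in self.alleles)

    def relabel(self, label: str) -> "Haplotype":
        return Haplotype(self.alleles, label)


Genotype = tuple  # unordered pair (a, b); compare as multisets


def genotype_key(g: Genotype) -> tuple:
    return tuple(sorted(g, key=_allele_key))


def genotype_to_str(g: Genotype) -> str:
    return "/".join(allele_to_str(a) for a in genotype_key(g))


@dataclass(frozen=True)
class SampleGenotypes:
    """Unphased genotypes of one sample aligned to a panel."""

    sample_id: str
    genotypes: tuple  # tuple of (a, b) pairs, len == panel length

    def __len__(self) -> int:
        return len(self.genotypes)

    def is_typed_at(self, i: int) -> bool:
        a, b = self.genotypes[i]
        return not (a is None and b is None)


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: int = 0  # 2 affected, 1 unaffected, 0 unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class Pedigree:
    individuals: tuple
    family_id: str = "FAM1"

    def __post_init__(self):
        ids = {i.id for i in self.individuals}
        if len(ids) != len(self.individuals):
            raise FileFormatError("duplicate individual ids in pedigree")
        for ind in self.individuals:
            for p in (ind.father, ind.mother):
                if p is not None and p not in ids:
                    raise FileFormatError(
                        f"individual {ind.id}: parent {p} not in pedigree"
                    )
        # cycle check via DFS over parent links
        state: dict = {}

        def visit(iid: str):
            if state.get(iid) == 1:
                raise FileFormatError("pedigree contains a cycle")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self[iid]
            for p in (ind.father, ind.mother):
                if p is not None:
                    visit(p)
            state[iid] = 2

        for ind in self.individuals:
            visit(ind.id)

    def __getitem__(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.id == iid:
                return ind
        raise KeyError(iid)

    def founders(self) -> tuple:
        return tuple(i for i in self.individuals if i.is_founder)

    def offspring(self) -> tuple:
        return tuple(i for i in self.individuals if not i.is_founder)

    def nuclear_family(self) -> tuple:
        """Validate single-nuclear-family structure.

        Returns ``(father_id, mother_id, offspring_ids)``.
        """
        founders = self.founders()
        kids = self.offspring()
        if len(founders) != 2 or not kids:
            raise FileFormatError(
                "expected a single nuclear family: exactly 2 founders and >=1 offspring"
            )
        f_ids = {f.id for f in founders}
        for k in kids:
            if {k.father, k.mother} != f_ids:
                raise FileFormatError(
                    f"offspring {k.id} is not a child of the two founders"
                )
        father = next((f.id for f in founders if f.sex == 1), None)
        mother = next((f.id for f in founders if f.sex == 2), None)
        if father is None or mother is None:
            # fall back to declared parent roles on the first offspring
            father, mother = kids[0].father, kids[0].mother
        return father, mother, tuple(k.id for k in kids)


# ---------------------------------------------------------------------------
# Panel IO


def parse_panel(path: Union[str, Path], name: Optional[str] = None) -> MarkerPanel:
    """Read a marker-panel TSV (columns: id chrom pos kind alleles mutation_site).

    Row order defines panel order.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"panel file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise FileFormatError(f"no markers in panel file {path}")
    header = lines[0].rstrip("\n").split("\t")
    required = {"id", "kind", "alleles"}
    if not required.issubset(header):
        raise FileFormatError(
            f"panel file {path} missing required columns {sorted(required - set(header))}"
        )
    col = {c: i for i, c in enumerate(header)}
    markers = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")

        def cell(c, default=""):
            i = col.get(c)
            return fields[i].strip() if i is not None and i < len(fields) else default

        mid = cell("id")
        kind = cell("kind")
        if kind not in ("snp", "microsatellite"):
            raise FileFormatError(f"{path}:{lineno}: unknown kind {kind!r}")
        alleles = frozenset(
            parse_allele_token(tok, kind, context=f"({path}:{lineno})")
            for tok in cell("alleles").split(",")
            if tok.strip()
        )
        pos_tok = cell("pos", "NA")
        pos = int(pos_tok) if pos_tok not in _MISSING_TOKENS else None
        markers.append(
            Marker(
                id=mid,
                kind=kind,
                chrom=cell("chrom", "21") or "21",
                pos=pos,
                alleles=alleles,
                is_mutation_site=cell("mutation_site", "0") in ("1", "true", "True"),
            )
        )
    if not markers:
        raise FileFormatError(f"no markers in panel file {path}")
    return MarkerPanel(tuple(markers), name=name or path.stem)


def write_panel(panel: MarkerPanel, path: Union[str, Path]) -> None:
    rows = ["id\tchrom\tpos\tkind\talleles\tmutation_site"]
    for m in panel:
        alleles = ",".join(
            allele_to_str(a) for a in sorted(m.alleles, key=_allele_key)
        )
        pos = "NA" if m.pos is None else str(m.pos)
        rows.append(
            f"{m.id}\t{m.chrom}\t{pos}\t{m.kind}\t{alleles}\t{int(m.is_mutation_site)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def default_panel() -> MarkerPanel:
    """The packaged 16-marker SOD1 panel (15 SNPs + CA repeat)."""
    with resources.as_file(
        resources.files("founderhap.data") / "sod1_panel16.tsv"
    ) as p:
        return parse_panel(p, name="sod1_panel16")


def subset_panel(
    panel: MarkerPanel,
    keep_ids: Optional[Sequence[str]] = None,
    preset: Optional[str] = None,
) -> MarkerPanel:
    """Sub-panel preserving relative order.

    ``preset="pop14"`` selects the 14 SNPs used for reference-population
    analyses (founder table minus the mutation site, no microsatellite).
    """
    if preset is not None:
        if preset != "pop14":
            raise FileFormatError(f"unknown panel preset {preset!r}")
        keep_ids = POP14_IDS
    if keep_ids is None:
        raise ValueError("either keep_ids or preset is required")
    keep = set(keep_ids)
    unknown = keep - set(panel.ids)
    if unknown:
        raise KeyError(f"unknown marker id(s): {sorted(unknown)}")
    markers = tuple(m for m in panel if m.id in keep)
    suffix = preset or "subset"
    return MarkerPanel(markers, name=f"{panel.name}.{suffix}")


def project_alleles(
    values: Sequence, src: MarkerPanel, dst: MarkerPanel
) -> tuple:
    """Reindex a per-marker vector from ``src`` onto ``dst`` (MISSING where absent)."""
    idx = {mid: i for i, mid in enumerate(src.ids)}
    out = []
    for mid in dst.ids:
        if mid in idx:
            out.append(values[idx[mid]])
        else:
            out.append(MISSING)
    return tuple(out)


# ---------------------------------------------------------------------------
# Pedigree / genotype IO


def parse_ped(path: Union[str, Path]) -> Pedigree:
    """Read a 6-column PED file (family id father mother sex phenotype)."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"PED file not found: {path}")
    individuals = []
    family_id = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split()
        if len(fields) < 6:
            raise FileFormatError(f"{path}:{lineno}: expected 6 PED columns")
        fam, iid, father, mother, sex, pheno = fields[:6]
        family_id = family_id or fam
        if fam != family_id:
            raise FileFormatError(f"{path}:{lineno}: multiple family ids")
        individuals.append(
            Individual(
                id=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
                affected=int(pheno) if pheno in ("0", "1", "2") else 0,
            )
        )
    if not individuals:
        raise FileFormatError(f"empty PED file {path}")
    return Pedigree(tuple(individuals), family_id=family_id or "FAM1")


def write_ped(ped: Pedigree, path: Union[str, Path]) -> None:
    rows = []
    for ind in ped.individuals:
        rows.append(
            "\t".join(
                [
                    ped.family_id,
                    ind.id,
                    ind.father or "0",
                    ind.mother or "0",
                    str(ind.sex),
                    str(ind.affected),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def parse_genotypes(
    path: Union[str, Path], panel: MarkerPanel
) -> list:
    """Read a long-format genotype TSV (sample marker_id allele1 allele2).

    Returns one :class:`SampleGenotypes` per sample (file order of first
    appearance); markers without a row are MISSING.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"genotype file not found: {path}")
    per_sample: dict = {}
    order: list = []
    lines = path.read_text().splitlines()
    if not lines:
        raise FileFormatError(f"empty genotype file {path}")
    start = 1 if lines[0].lower().startswith("sample") else 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 4:
            raise FileFormatError(f"{path}:{lineno}: expected 4 columns")
        sample, mid, a1, a2 = (f.strip() for f in fields[:4])
        if mid not in panel:
            raise FileFormatError(f"{path}:{lineno}: marker {mid!r} not in panel")
        kind = panel.get(mid).kind
        g = (
            parse_allele_token(a1, kind, context=f"({path}:{lineno})"),
            parse_allele_token(a2, kind, context=f"({path}:{lineno})"),
        )
        if any(is_ambiguous(a) for a in g):
            raise FileFormatError(
                f"{path}:{lineno}: ambiguous alleles not allowed in genotypes"
            )
        if sample not in per_sample:
            per_sample[sample] = [(MISSING, MISSING)] * len(panel)
            order.append(sample)
        per_sample[sample][panel.index_of(mid)] = g
    return [SampleGenotypes(s, tuple(per_sample[s])) for s in order]


def write_genotypes(
    samples: Iterable[SampleGenotypes], panel: MarkerPanel, path: Union[str, Path]
) -> None:
    rows = ["sample\tmarker_id\tallele1\tallele2"]
    for sg in samples:
        for mid, (a, b) in zip(panel.ids, sg.genotypes):
            if a is None and b is None:
                continue
            rows.append(
                f"{sg.sample_id}\t{mid}\t{allele_to_str(a)}\t{allele_to_str(b)}"
            )
    Path(path).write_text("\n".join(rows) + "\n")
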