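"""Exhaustive Mendelian-constrained phasing of a nuclear family.

The family data are genotypes over a short marker panel around a gene; the
region is assumed to be transmitted without recombination within the family
(one generation, a few hundred kb), so each offspring inherits one complete
parental haplotype from each parent.  Phasing is an exact constraint search:

1. fix a transmission vector (which of each parent's two haplotypes each
   genotyped offspring received);
2. given the transmission vector, markers decouple: solve each marker by
   unifying the four parental allele slots against the parental genotypes
   (when typed) and every offspring genotype;
3. the solutions for a transmission vector are the cross product of the
   per-marker assignments; the full solution set is the union over feasible
   transmission vectors, deduplicated up to within-parent haplotype swaps.

The search keeps the factored form (transmission vector x per-marker
assignment sets): forced positions, the carrier background and the family
haplotype set are read off without expanding the cross product, which can be
astronomically large when both parents are ungenotyped and many markers are
phase-ambiguous.  Materializing the explicit solution list
(:attr:`PhaseResult.solutions`) is subject to the configuration cap.

Ungenotyped founders (e.g. deceased parents) have free haplotypes constrained
only through their offspring; slots never pinned by any constraint remain
MISSING.  Obligate carrier / non-carrier status is an input annotation, not
inferred from affection status.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import EnumerationCapError, MendelianError, NoCarrierError
from .model import (
    MISSING,
    Haplotype,
    MarkerPanel,
    Pedigree,
    SampleGenotypes,
    allele_sort_key,
)

_FREE = object()  # unification sentinel: slot not yet pinned


@dataclass(frozen=True)
class PhaseSolution:
    """One complete zero-recombination phase assignment for the family."""

    father_id: str
    mother_id: str
    father: Tuple[Haplotype, Haplotype]
    mother: Tuple[Haplotype, Haplotype]
    #: genotyped offspring id -> (paternal haplotype index, maternal index)
    transmissions: Mapping[str, Tuple[int, int]]

    def haplotype_of(self, sample_id: str, parent: str) -> Haplotype:
        p, m = self.transmissions[sample_id]
        return self.father[p] if parent == "father" else self.mother[m]

    def all_haplotypes(self) -> Tuple[Haplotype, ...]:
        return (*self.father, *self.mother)


class PhaseResult:
    """All zero-recombination phasings, in factored form.

    ``groups`` pairs each feasible transmission vector with its per-marker
    assignment lists; a full solution is one assignment choice per marker.
    """

    def __init__(
        self,
        father_id: str,
        mother_id: str,
        typed_offspring: tuple,
        groups: tuple,
        family_haplotype_set: tuple,
        n_configurations: int,
        max_configs: int,
    ):
        self.father_id = father_id
        self.mother_id = mother_id
        self.typed_offspring = typed_offspring
        self.groups = groups
        self.family_haplotype_set = family_haplotype_set
        self.n_configurations = n_configurations
        self.max_configs = max_configs
        self._solutions: Optional[tuple] = None

    @property
    def solutions(self) -> tuple:
        """Explicit deduplicated solution list (subject to the cap)."""
        if self._solutions is None:
            if self.n_configurations > self.max_configs:
                raise EnumerationCapError(
                    f"phase enumeration would expand {self.n_configurations} "
                    f"configurations (cap {self.max_configs}); subset the "
                    "marker panel or genotype more individuals"
                )
            self._solutions = self._materialize()
        return self._solutions

    def __len__(self) -> int:
        return len(self.solutions)

    def _materialize(self) -> tuple:
        seen = set()
        out = []
        for tvec, per_marker in self.groups:
            for combo in itertools.product(*per_marker):
                f0 = tuple(a[0] for a in combo)
                f1 = tuple(a[1] for a in combo)
                m0 = tuple(a[2] for a in combo)
                m1 = tuple(a[3] for a in combo)
                fpair, mpair, ctvec = _canonical((f0, f1), (m0, m1), tvec)
                key = (fpair, mpair, ctvec)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    PhaseSolution(
                        father_id=self.father_id,
                        mother_id=self.mother_id,
                        father=(Haplotype(fpair[0]), Haplotype(fpair[1])),
                        mother=(Haplotype(mpair[0]), Haplotype(mpair[1])),
                        transmissions=dict(zip(self.typed_offspring, ctvec)),
                    )
                )
        out.sort(key=_solution_sort_key)
        return tuple(out)


def _solution_sort_key(s: PhaseSolution):
    return (
        tuple(sorted(s.transmissions.items())),
        tuple(tuple(allele_sort_key(a) for a in h.alleles) for h in s.all_haplotypes()),
    )


def _orderings(genotype):
    """Ordered interpretations of an unordered genotype pair (MISSING = free)."""
    a, b = genotype
    a = _FREE if a is None else a
    b = _FREE if b is None else b
    if a is b or a == b:
        return [(a, b)]
    return [(a, b), (b, a)]


def _solve_marker(father_g, mother_g, kid_gs):
    """All consistent per-marker slot assignments.

    Returns ``(bits, (f0, f1, m0, m1))`` pairs where ``bits`` holds one
    ``(bp, bm)`` per genotyped offspring — or ``None`` when that offspring is
    untyped at this marker (wildcard).  Slot values are alleles or ``None``
    (never pinned by any constraint).
    """
    father_opts = [(_FREE, _FREE)] if father_g is None else _orderings(father_g)
    mother_opts = [(_FREE, _FREE)] if mother_g is None else _orderings(mother_g)
    results = set()

    def backtrack(ki, f, m, bits):
        if ki == len(kid_gs):
            assign = tuple(None if s is _FREE else s for s in (*f, *m))
            results.add((tuple(bits), assign))
            return
        g = kid_gs[ki]
        if g is None or (g[0] is None and g[1] is None):
            backtrack(ki + 1, f, m, bits + [None])
            return
        for bp in (0, 1):
            for bm in (0, 1):
                for pa, ma in _orderings(g):
                    f2, m2 = list(f), list(m)
                    ok = True
                    for slots, idx, val in ((f2, bp, pa), (m2, bm, ma)):
                        if val is _FREE:
                            continue
                        if slots[idx] is _FREE:
                            slots[idx] = val
                        elif slots[idx] != val:
                            ok = False
                            break
                    if ok:
                        backtrack(ki + 1, f2, m2, bits + [(bp, bm)])

    for f in father_opts:
        for m in mother_opts:
            backtrack(0, list(f), list(m), [])
    return sorted(results, key=repr)


def _bits_match(pattern, tvec) -> bool:
    return all(p is None or p == t for p, t in zip(pattern, tvec))


def _canonical(father_pair, mother_pair, tvec):
    """Canonical form under within-parent haplotype swaps."""
    best = None
    for sf in (0, 1):
        for sm in (0, 1):
            f = (father_pair[sf], father_pair[1 - sf])
            m = (mother_pair[sm], mother_pair[1 - sm])
            t = tuple((bp ^ sf, bm ^ sm) for bp, bm in tvec)
            key = (
                tuple(tuple(allele_sort_key(a) for a in h) for h in f),
                tuple(tuple(allele_sort_key(a) for a in h) for h in m),
                t,
            )
            if best is None or key < best[0]:
                best = (key, (f, m, t))
    return best[1]


def enumerate_phasings(
    ped: Pedigree,
    genos: Sequence[SampleGenotypes],
    panel: MarkerPanel,
    *,
    mutation_marker: Optional[str] = None,
    mutant_allele=None,
    obligate_carriers: Iterable[str] = (),
    obligate_noncarriers: Iterable[str] = (),
    max_configs: int = 10**6,
) -> PhaseResult:
    """All phase solutions consistent with Mendelian transmission, exactly.

    ``obligate_carriers`` / ``obligate_noncarriers`` name founders whose
    carrier status at ``mutation_marker`` is known externally (an affected
    deceased parent; a married-in non-carrier parent); assignments where the
    annotation is visibly violated are discarded (MISSING slots cannot
    falsify an annotation).

    Raises :class:`MendelianError` when no solution exists.  The explicit
    solution list is materialized lazily and raises
    :class:`EnumerationCapError` beyond ``max_configs`` configurations.
    """
    father_id, mother_id, kid_ids = ped.nuclear_family()
    annotated = set(obligate_carriers) | set(obligate_noncarriers)
    if annotated and (mutation_marker is None or mutant_allele is None):
        raise ValueError("carrier annotations require mutation_marker and mutant_allele")
    if annotated - {father_id, mother_id}:
        raise ValueError("obligate carrier annotations apply to founders only")

    geno_by_id = {sg.sample_id: sg for sg in genos}
    unknown = set(geno_by_id) - {i.id for i in ped.individuals}
    if unknown:
        raise MendelianError(f"genotyped sample(s) not in pedigree: {sorted(unknown)}")
    if not geno_by_id:
        raise MendelianError("no genotyped individual in the family")
    typed_kids = tuple(k for k in kid_ids if k in geno_by_id)

    def geno_at(iid, m):
        sg = geno_by_id.get(iid)
        if sg is None:
            return None
        g = sg.genotypes[m]
        return None if (g[0] is None and g[1] is None) else g

    mut_idx = panel.index_of(mutation_marker) if mutation_marker else None
    if mut_idx is not None:
        for iid in obligate_carriers:
            g = geno_at(iid, mut_idx)
            if g is not None and mutant_allele not in g:
                raise MendelianError(
                    f"obligate carrier {iid} lacks {mutant_allele!r} at {mutation_marker}"
                )
        for iid in obligate_noncarriers:
            g = geno_at(iid, mut_idx)
            if g is not None and mutant_allele in g:
                raise MendelianError(
                    f"obligate non-carrier {iid} carries {mutant_allele!r} at {mutation_marker}"
                )

    marker_solutions = []
    for m in range(len(panel)):
        sols = _solve_marker(
            geno_at(father_id, m),
            geno_at(mother_id, m),
            [geno_at(k, m) for k in typed_kids],
        )
        if m == mut_idx and annotated:
            sols = [
                ba
                for ba in sols
                if _annotation_ok(
                    ba[1],
                    father_id,
                    mother_id,
                    mutant_allele,
                    set(obligate_carriers),
                    set(obligate_noncarriers),
                )
            ]
            if not sols:
                raise MendelianError(
                    f"no phasing at {mutation_marker} satisfies the carrier annotations"
                )
        if not sols:
            trio = _blame_trio(father_id, mother_id, typed_kids, geno_at, m)
            raise MendelianError(
                f"Mendelian inconsistency at marker {panel.ids[m]} "
                f"(trio {trio[0]} x {trio[1]} -> {trio[2]})"
            )
        marker_solutions.append(sols)

    total = 0
    groups = []
    for tvec in itertools.product(itertools.product((0, 1), repeat=2), repeat=len(typed_kids)):
        per_marker = []
        ok = True
        for sols in marker_solutions:
            assigns = sorted(
                {a for bits, a in sols if _bits_match(bits, tvec)}, key=repr
            )
            if not assigns:
                ok = False
                break
            per_marker.append(tuple(assigns))
        if not ok:
            continue
        count = 1
        for assigns in per_marker:
            count *= len(assigns)
        total += count
        groups.append((tvec, tuple(per_marker)))

    if not groups:
        raise MendelianError(
            "genotypes admit no zero-recombination phasing "
            "(per-marker constraints conflict across markers)"
        )

    family_set = None
    for tvec, per_marker in groups:
        determined = set()
        for slot in range(4):
            vec = []
            for assigns in per_marker:
                vals = {a[slot] for a in assigns}
                if len(vals) != 1 or None in vals:
                    vec = None
                    break
                vec.append(next(iter(vals)))
            if vec is not None:
                determined.add(tuple(vec))
        family_set = determined if family_set is None else family_set & determined
    family_haps = tuple(
        Haplotype(v)
        for v in sorted(
            family_set or (), key=lambda v: tuple(allele_sort_key(a) for a in v)
        )
    )
    return PhaseResult(
        father_id=father_id,
        mother_id=mother_id,
        typed_offspring=typed_kids,
        groups=tuple(groups),
        family_haplotype_set=family_haps,
        n_configurations=total,
        max_configs=max_configs,
    )


def _annotation_ok(assign, father_id, mother_id, mutant_allele, carriers, noncarriers):
    """Check founder carrier annotations on one mutation-site assignment."""
    slots = {father_id: assign[0:2], mother_id: assign[2:4]}
    for iid in carriers:
        pair = slots[iid]
        if all(a is not None and a != mutant_allele for a in pair):
            return False
    for iid in noncarriers:
        if mutant_allele in slots[iid]:
            return False
    return True


def _blame_trio(father_id, mother_id, typed_kids, geno_at, m):
    """Identify an offspring violating single-trio Mendelian rules at marker m."""
    fg, mg = geno_at(father_id, m), geno_at(mother_id, m)
    for k in typed_kids:
        kg = geno_at(k, m)
        if kg is None:
            continue
        ok = False
        for pa, ma in ((kg[0], kg[1]), (kg[1], kg[0])):
            pat_ok = fg is None or pa is None or pa in fg
            mat_ok = mg is None or ma is None or ma in mg
            if pat_ok and mat_ok:
                ok = True
                break
        if not ok:
            return (father_id, mother_id, k)
    return (father_id, mother_id, typed_kids[0] if typed_kids else "?")


def carrier_background(
    pr: PhaseResult,
    panel: MarkerPanel,
    mutation_marker: str,
    mutant_allele,
    carriers: Sequence[str],
) -> Haplotype:
    """The haplotype carrying the mutant allele shared by all carriers.

    Considers every phase solution in which one founder haplotype bears the
    mutant allele and reaches every named carrier (a carrier founder must own
    it; a carrier offspring must have received it).  Positions forced to the
    same allele across all such placements are reported; positions the
    solutions disagree on are MISSING.  Works on the factored solution
    representation, so it never expands the cross product.
    """
    if not carriers:
        raise NoCarrierError("no carriers named")
    mut_idx = panel.index_of(mutation_marker)
    founder_of_slot = {0: pr.father_id, 1: pr.father_id, 2: pr.mother_id, 3: pr.mother_id}
    position_values: list = [set() for _ in range(len(panel))]
    any_candidate = False
    for tvec, per_marker in pr.groups:
        for slot in range(4):
            owner = founder_of_slot[slot]
            ok = True
            for c in carriers:
                if c == owner:
                    continue
                if c in (pr.father_id, pr.mother_id):
                    ok = False  # carrier is the other founder
                    break
                if c not in pr.typed_offspring:
                    ok = False
                    break
                bp, bm = tvec[pr.typed_offspring.index(c)]
                received = bp if slot < 2 else 2 + bm
                if received != slot:
                    ok = False
                    break
            if not ok:
                continue
            mut_assigns = [a for a in per_marker[mut_idx] if a[slot] == mutant_allele]
            if not mut_assigns:
                continue
            any_candidate = True
            for m, assigns in enumerate(per_marker):
                use = mut_assigns if m == mut_idx else assigns
                position_values[m].update(a[slot] for a in use)
    if not any_candidate:
        raise NoCarrierError(
            f"no phase solution places allele {mutant_allele!r} at "
            f"{mutation_marker} on a haplotype shared by all carriers"
        )
    merged = tuple(
        next(iter(vals)) if len(vals) == 1 else MISSING for vals in position_values
    )
    return Haplotype(merged, label=f"{mutation_marker}:{mutant_allele} background")
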