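"""Independent brute-force oracles used by the tests.

These deliberately share no code with the implementation paths they check:
the phasing oracle enumerates all 2^(het sites) allele orderings per parent
and filters by transmission; the LD oracle recounts joint haplotype
frequencies and uses the squared indicator correlation.
"""

import itertools

import numpy as np

from founderhap.model import (
    Individual,
    Marker,
    MarkerPanel,
    Pedigree,
    SampleGenotypes,
    genotype_key,
)
def canonical_form(father_pair, mother_pair, tvec):
    """Normalize a solution under within-parent haplotype swaps.

    Written independently of the implementation's normalizer: enumerates the
    four swap combinations and keeps the lexicographically smallest, flipping
    transmission bits to match.
    """
    variants = []
    for sf in (0, 1):
        for sm in (0, 1):
            f = (father_pair[sf], father_pair[1 - sf])
            m = (mother_pair[sm], mother_pair[1 - sm])
            t = tuple((bp ^ sf, bm ^ sm) for bp, bm in tvec)
            variants.append((repr((f, m, t)), (f, m, t)))
    return min(variants)[1]


def random_typed_family(rng, n_markers, n_kids, alleles=("A", "C")):
    """A random fully-genotyped nuclear family (Mendelian by construction)."""
    panel = MarkerPanel(
        tuple(
            Marker(id=f"m{i}", kind="snp", alleles=frozenset(alleles))
            for i in range(n_markers)
        )
    )
    father = [tuple(rng.choice(alleles, n_markers)) for _ in range(2)]
    mother = [tuple(rng.choice(alleles, n_markers)) for _ in range(2)]
    kid_genos = []
    truth = []
    for _ in range(n_kids):
        bp, bm = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        truth.append((bp, bm))
        kid_genos.append(
            tuple(
                genotype_key((father[bp][i], mother[bm][i]))
                for i in range(n_markers)
            )
        )
    ped = Pedigree(
        (
            Individual("F", sex=1),
            Individual("M", sex=2),
            *[Individual(f"K{k}", father="F", mother="M") for k in range(n_kids)],
        )
    )
    genos = [
        SampleGenotypes(
            "F",
            tuple(genotype_key((father[0][i], father[1][i])) for i in range(n_markers)),
        ),
        SampleGenotypes(
            "M",
            tuple(genotype_key((mother[0][i], mother[1][i])) for i in range(n_markers)),
        ),
    ] + [SampleGenotypes(f"K{k}", kid_genos[k]) for k in range(n_kids)]
    return panel, ped, genos, (father, mother, truth)


def phase_oracle(genos, kid_ids, n_markers):
    """Naive exhaustive phasing for a fully-typed family.

    Enumerates every ordering of each parent's genotype vector and every
    transmission vector, keeps the Mendelian-consistent ones, and returns the
    canonicalized solution set.
    """
    by = {g.sample_id: g.genotypes for g in genos}

    def orderings(gt):
        opts = [[(a, b), (b, a)] if a != b else [(a, b)] for a, b in gt]
        return {tuple(zip(*o)) for o in itertools.product(*opts)}

    sols = set()
    for f in orderings(by["F"]):
        for m in orderings(by["M"]):
            for tvec in itertools.product(
                itertools.product((0, 1), repeat=2), repeat=len(kid_ids)
            ):
                ok = True
                for kid, (bp, bm) in zip(kid_ids, tvec):
                    for i in range(n_markers):
                        if genotype_key((f[bp][i], m[bm][i])) != genotype_key(
                            by[kid][i]
                        ):
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    sols.add(canonical_form(f, m, tvec))
    return sols


def solution_set(pr):
    """The implementation's solutions in the oracle's canonical coordinates."""
    return {
        canonical_form(
            tuple(h.alleles for h in s.father),
            tuple(h.alleles for h in s.mother),
            tuple(s.transmissions[k] for k in pr.typed_offspring),
        )
        for s in pr.solutions
    }


def r2_indicator_oracle(haps, i, j):
    """r^2 as the squared Pearson correlation of 0/1 major-allele indicators."""
    from founderhap.ld import _column, _major_allele

    col_i, col_j = _column(haps, i), _column(haps, j)
    a, _ = _major_allele(col_i)
    b, _ = _major_allele(col_j)
    x = np.array([1.0 if v == a else 0.0 for v in col_i])
    y = np.array([1.0 if v == b else 0.0 for v in col_j])
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)
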