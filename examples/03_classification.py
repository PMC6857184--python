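"""Classify a patient's genotypes against a reference haplotype spectrum.

Which reference haplotypes could each chromosome of the proband be?  A
reference is 'compatible' when one genotype allele matches it at every
marker; with the mutation constraint, the mutant background extracted from
the family must additionally equal the reference at all co-observed sites.
The proband here is compatible with exactly one haplotype — the most common
one (rank 1), so the mutation rides background "1" and is labelled 1V.
"""

from importlib import resources

import founderhap as fh
from founderhap.model import project_alleles
from founderhap.population import build_spectrum

panel = fh.default_panel()
pop14 = fh.subset_panel(panel, preset="pop14")

# an Iberian-like reference spectrum (counts per 100 chromosomes)
idx = [panel.index_of(m) for m in pop14.ids]
haps = []
for w, (h, _) in zip((45, 20, 12, 8, 6, 4, 3, 2), fh.ibs_like_spectrum(panel)):
    haps += [tuple(h[i] for i in idx)] * w
spectrum = build_spectrum(haps, label="IBS-like", panel=pop14)

with resources.as_file(resources.files("founderhap.data") / "sod1_family_table1.ped") as p:
    ped = fh.parse_ped(p)
with resources.as_file(
    resources.files("founderhap.data") / "sod1_family_table1_genotypes.tsv"
) as p:
    genos = fh.parse_genotypes(p, panel)

pr = fh.enumerate_phasings(
    ped, genos, panel,
    mutation_marker=fh.MUTATION_MARKER, mutant_allele=fh.MUTANT_ALLELE,
    obligate_carriers=["I:1"], obligate_noncarriers=["I:2"],
)
bg = fh.carrier_background(
    pr, panel, fh.MUTATION_MARKER, fh.MUTANT_ALLELE, ["I:1", "II:1", "II:5"]
)
bg14 = fh.Haplotype(project_alleles(bg.alleles, panel, pop14))

proband = genos[0]
first = project_alleles([g[0] for g in proband.genotypes], panel, pop14)
second = project_alleles([g[1] for g in proband.genotypes], panel, pop14)
res = fh.compatible_references(
    fh.SampleGenotypes(proband.sample_id, tuple(zip(first, second))),
    spectrum,
    mutation_marker=fh.MUTATION_MARKER, mutant_allele=fh.MUTANT_ALLELE,
    carrier_background=bg14,
)
print(f"references compatible with {proband.sample_id}: {res.n_compatible}")
for e in res.compatible_entries():
    print(f"  rank {e.rank_name}: {e.reference.to_str()}")
    print(f"  -> mutant background label: {e.rank_name}V")
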