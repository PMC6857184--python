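"""Phase the published ALS family and extract the mutant founder background.

Uses the packaged genotypes of the two affected brothers (heterozygous
T/C at rs121912442, the SOD1 p.A5V mutation) with the deceased father as
obligate carrier.  Mendelian constraints force the complete haplotype the
mutation rides on; comparing it with the published founder haplotypes shows
it is identical to the Swedish (European) background and differs from the
North American one at 9 of 14 co-typed sites.
"""

from importlib import resources

import founderhap as fh

panel = fh.default_panel()
with resources.as_file(resources.files("founderhap.data") / "sod1_family_table1.ped") as p:
    ped = fh.parse_ped(p)
with resources.as_file(
    resources.files("founderhap.data") / "sod1_family_table1_genotypes.tsv"
) as p:
    genos = fh.parse_genotypes(p, panel)

result = fh.enumerate_phasings(
    ped, genos, panel,
    mutation_marker=fh.MUTATION_MARKER, mutant_allele=fh.MUTANT_ALLELE,
    obligate_carriers=["I:1"],      # the affected, deceased father
    obligate_noncarriers=["I:2"],   # the married-in mother
)
background = fh.carrier_background(
    result, panel, fh.MUTATION_MARKER, fh.MUTANT_ALLELE, ["I:1", "II:1", "II:5"]
)
print("phase solutions:", len(result.solutions))
print("carrier background:", background.to_str())
print("(order:", ", ".join(panel.ids), ")")

founders = fh.default_founders(panel)
for label in ("SWE", "USA", "IBS"):
    mm = fh.mismatch(background, founders[label])
    print(f"vs {label}: {mm['n_mismatch']} mismatches over {mm['n_compared']} sites")
print("\n0 mismatches vs SWE/IBS and 9 vs USA places this family on the "
      "European founder background.")
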