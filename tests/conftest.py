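from importlib import resources

import pytest

import founderhap as fh


def data_path(name):
    return resources.as_file(resources.files("founderhap.data") / name)


@pytest.fixture(scope="session")
def panel16():
    return fh.default_panel()


@pytest.fixture(scope="session")
def pop14(panel16):
    return fh.subset_panel(panel16, preset="pop14")


@pytest.fixture(scope="session")
def founders(panel16):
    return fh.default_founders(panel16)


@pytest.fixture(scope="session")
def table1_family(panel16):
    """The published family: PED plus the two printed patient genotypes."""
    with data_path("sod1_family_table1.ped") as p:
        ped = fh.parse_ped(p)
    with data_path("sod1_family_table1_genotypes.tsv") as p:
        genos = fh.parse_genotypes(p, panel16)
    return ped, genos


@pytest.fixture(scope="session")
def table1_phase(panel16, table1_family):
    ped, genos = table1_family
    return fh.enumerate_phasings(
        ped,
        genos,
        panel16,
        mutation_marker=fh.MUTATION_MARKER,
        mutant_allele=fh.MUTANT_ALLELE,
        obligate_carriers=["I:1"],
        obligate_noncarriers=["I:2"],
    )


@pytest.fixture()
def fixture_dir(tmp_path):
    """A small synthetic fixture bundle on disk (seed 7)."""
    cfg = fh.default_config(7)
    paths = fh.write_fixture_set(cfg, tmp_path / "fix")
    return cfg, paths
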