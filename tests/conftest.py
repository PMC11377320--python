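import pytest
from hypothesis import HealthCheck, settings

from pvsignal import deduplicate, link_tables, synthetic_faers

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_tables():
    return synthetic_faers.fixture_small()


@pytest.fixture(scope="session")
def fixture_cases(fixture_tables):
    return deduplicate(link_tables(fixture_tables))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_tables):
    """The small fixture written to disk in the FAERS dialect, with the
    synonym and PT->SOC side files."""
    d = tmp_path_factory.mktemp("fixture_small")
    synthetic_faers.write_dataset(fixture_tables, d)
    with open(d / "synonyms.txt", "w") as fh:
        fh.write("raw\tcanonical\n")
        for k, v in synthetic_faers.FIXTURE_SYNONYMS.items():
            fh.write(f"{k}\t{v}\n")
    with open(d / "pt_soc_map.txt", "w") as fh:
        fh.write("pt\tsoc\n")
        for k, v in synthetic_faers.FIXTURE_PT_SOC.items():
            fh.write(f"{k}\t{v}\n")
    return d
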