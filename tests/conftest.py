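import pytest
from hypothesis import HealthCheck, settings

from popdiff import PipelineConfig, run_pipeline, table2_fixture

settings.register_profile(
    "popdiff",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("popdiff")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The 18-SNP reference cohort files (vcf, gme, clinvar)."""
    out = tmp_path_factory.mktemp("table2_fixture")
    return table2_fixture(out)


@pytest.fixture(scope="session")
def fixture_run(fixture_paths, tmp_path_factory):
    """Pipeline results and funnel for the reference cohort at defaults."""
    vcf, gme, clinvar = fixture_paths
    out = tmp_path_factory.mktemp("table2_report")
    config = PipelineConfig(
        vcf_path=vcf, gme_path=gme, clinvar_path=clinvar, output_dir=out
    )
    results, funnel = run_pipeline(config)
    return results, funnel, out
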