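import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gene_models():
    from irdyield.paneldata import default_gene_models

    return default_gene_models()


def make_case(pid="P1", ancestry="chinese", sex="female", exam=50.0,
              onset=30.0, relatives=0, phenotype="retinitis_pigmentosa",
              variants=(), status=None):
    """Small ProbandCase builder for analytics tests."""
    from irdyield.analytics import ProbandCase

    return ProbandCase(
        proband_id=pid, ancestry=ancestry, sex=sex, age_at_exam=exam,
        age_of_onset=onset, affected_relatives=relatives,
        phenotype=phenotype, variants=list(variants), status=status,
    )


def solved_case(pid, gene, phenotype, fully=True, variants=(), **kwargs):
    from irdyield.resolution import SolvedStatus, Status

    status = SolvedStatus(
        Status.FULLY_SOLVED if fully else Status.PROBABLY_SOLVED, gene, False)
    return make_case(pid=pid, phenotype=phenotype, variants=variants,
                     status=status, **kwargs)


def unsolved_case(pid, **kwargs):
    from irdyield.resolution import SolvedStatus, Status

    return make_case(pid=pid, status=SolvedStatus(Status.UNSOLVED, None, False),
                     **kwargs)
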