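import pytest

from methexpr.synthdata import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted cohort for fast structural tests."""
    cfg = SimConfig(
        n_case=30,
        n_control=30,
        n_genes=200,
        probes_per_region=1,
        n_intergenic=150,
        n_hypo_up=10,
        n_diff_intergenic=30,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: no planted classes, no differential CpGs."""
    cfg = SimConfig(
        n_case=30,
        n_control=30,
        n_genes=300,
        probes_per_region=1,
        n_intergenic=100,
        n_hypo_up=0,
        n_diff_intergenic=0,
        expr_effect=0.0,
        meth_effect=0.0,
        seed=5,
    )
    return generate_cohort(cfg)
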