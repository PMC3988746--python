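import numpy as np
import pytest

from recprobit import (
    EquationSpec,
    GeneratorConfig,
    ModelSpec,
    RecursiveBivariateProbit,
    SmoothSpec,
    generate,
)


@pytest.fixture(scope="session")
def case_spec():
    """Case-study-shaped specification: smooth ischaemic-time effect in eq 1."""
    return ModelSpec(
        treatment="STres",
        outcome="mortality",
        eq1=EquationSpec(parametric=("access", "age"), smooths=(SmoothSpec("O2B", 10),)),
        eq2=EquationSpec(parametric=("killip", "EF")),
    )


@pytest.fixture(scope="session")
def nospline_spec():
    return ModelSpec(
        treatment="STres",
        outcome="mortality",
        eq1=EquationSpec(parametric=("access", "age")),
        eq2=EquationSpec(parametric=("killip", "EF")),
    )


@pytest.fixture(scope="session")
def ds_confounded():
    """One confounded synthetic cohort (gamma=-1, rho=0.4, n=3000)."""
    return generate(GeneratorConfig(n=3000, gamma=-1.0, rho=0.4, seed=42))


@pytest.fixture(scope="session")
def fitted_confounded(ds_confounded, case_spec):
    model = RecursiveBivariateProbit(ds_confounded.frame, case_spec)
    return model.fit()


@pytest.fixture(scope="session")
def toy_model():
    """Tiny (n=50) model with a smooth, for derivative checks."""
    ds = generate(GeneratorConfig(n=50, gamma=-1.0, rho=0.4, seed=3))
    spec = ModelSpec(
        treatment="STres",
        outcome="mortality",
        eq1=EquationSpec(parametric=("access", "age"), smooths=(SmoothSpec("O2B", 6),)),
        eq2=EquationSpec(parametric=("killip", "EF")),
    )
    return RecursiveBivariateProbit(ds.frame, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
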