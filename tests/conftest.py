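import pytest

from goldilocks.models import (
    CleavageRates,
    FoldingThreeState,
    FoldingTwoState,
    ModelSpec,
)


@pytest.fixture
def rel_two_state() -> ModelSpec:
    """The reference two-state landscape in relative units (k_u = 1,
    k_f = 0.2, midpoint at 1, n = 4.1)."""
    return ModelSpec(
        states=2,
        folding=FoldingTwoState(K_D=1.0, n=4.1),
        rates=CleavageRates(k_u=1.0, k_f=0.2),
        units="relative",
    )


@pytest.fixture
def rel_three_state() -> ModelSpec:
    """Three-state scenario base: transitions at 1 and 2 [Mg2+]_rel,
    n1 = n2 = 4.1, k_u/k_f = 5."""
    return ModelSpec(
        states=3,
        folding=FoldingThreeState(K_D1=1.0, n1=4.1, K_D2=2.0, n2=4.1),
        rates=CleavageRates(k_u=1.0, k_i=0.5, k_f=0.2),
        units="relative",
    )
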