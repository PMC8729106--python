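import numpy as np
import pytest

from grnsync import (
    GeneSpec,
    InputSpec,
    NetworkSpec,
    SpeciesRef,
    TFBindingSpec,
)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def constitutive_gene_network():
    """One unregulated gene: dn/dt = nu - delta*n."""
    gene = GeneSpec(product=SpeciesRef("P"), logic="single", nu=0.05, delta=1e-3)
    return NetworkSpec(genes=(gene,))


@pytest.fixture
def single_activated_gene_network():
    """One gene activated by a constant input."""
    gene = GeneSpec(
        product=SpeciesRef("P"),
        logic="single",
        nu=0.05,
        delta=1e-3,
        bindings=(TFBindingSpec(SpeciesRef("A", "input"), 1e-4, 1e-2),),
    )
    inp = InputSpec(SpeciesRef("A", "input"), "constant", amplitude=100.0)
    return NetworkSpec(inputs=(inp,), genes=(gene,))
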