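import numpy as np
import pytest

import sdmax
from sdmax import GridStack, GridTransform


@pytest.fixture
def small_stack():
    """3-layer 10x10 stack with one NoData hole, unit cells, origin (0, 10)."""
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(3, 10, 10))
    vals[1, 4, 7] = np.nan  # hole invalidates the cell in every layer
    return GridStack(
        layer_names=["alt", "slope", "solar"],
        values=vals,
        transform=GridTransform(x_origin=0.0, y_origin=10.0, cell=1.0),
    )


@pytest.fixture(scope="session")
def virtual_species():
    """A landscape + known-truth species used across fitting/eval tests.

    Two informative layers (coefficients 2.0 and -1.5 on standardized
    values) and two pure-noise layers; 500 presences; 2000 background.
    """
    stack = sdmax.generate_landscape(4, (80, 80), smooth_radius=2.5, seed=11)
    truth = sdmax.TrueModel(linear={"env1": 2.0, "env2": -1.5})
    suit = sdmax.true_suitability(stack, truth)
    occ = sdmax.sample_presences(suit, stack, 500, seed=12)
    presences = sdmax.extract_values(stack, occ)
    background = sdmax.sample_background(stack, 2000, seed=13)
    return {
        "stack": stack,
        "truth": truth,
        "suitability": suit,
        "occurrences": occ,
        "presences": presences,
        "background": background,
    }


@pytest.fixture(scope="session")
def fitted_model(virtual_species):
    """Linear-feature fit of the virtual species (spec, model, trace, P, B)."""
    spec = sdmax.FeatureSpec.from_background(
        virtual_species["background"], classes=("linear",)
    )
    P = spec.build(virtual_species["presences"])
    B = spec.build(virtual_species["background"])
    model, trace = sdmax.fit_maxent(P, B, spec, beta0=0.05)
    return {"spec": spec, "model": model, "trace": trace, "P": P, "B": B}
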