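import pandas as pd
import pytest

from senrev import (
    DEFAULT_PARAMS,
    EffectMap,
    LayoutSpec,
    generate_screen,
    reversal_effect,
)

LIBRARY_40 = [f"si{i + 1:03d}" for i in range(40)]


@pytest.fixture(scope="session")
def small_screen():
    """40-siRNA single-arm screen with one planted +4/-4 SD reverser."""
    effects = EffectMap(shifts={"si001": reversal_effect(4.0)})
    cells, layout, truth = generate_screen(
        LIBRARY_40,
        LayoutSpec(arms=("Group1",), replicates=3),
        DEFAULT_PARAMS,
        effects,
        seed=7,
    )
    return cells, layout, truth


@pytest.fixture
def tiny_layout():
    """Two-well single-plate layout: one siGLO control, one test siRNA."""
    return pd.DataFrame(
        {
            "plate": ["P1", "P1"],
            "well": ["A1", "A2"],
            "sirna": ["siGLO", "siTEST"],
            "dose_nM": [30.0, 30.0],
            "arm": ["control", "Group1"],
            "replicate": [1, 1],
        }
    )
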