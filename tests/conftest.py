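import numpy as np
import pytest

from pgxscreen.simulate import (
    CohortSpec,
    CnvEffect,
    SnvEffect,
    SyntheticTruth,
    generate_cohort,
    panel_for_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture(scope="session")
def planted_cohort():
    """One cohort with three strong planted SNV effects and one CNV slope.

    Effect genes sit at mutation frequency 0.3 so both groups are large; the
    effects (δ = 2 pooled SD) are strong enough that the strict consensus
    rule recovers exactly these genes at this seed.
    """
    spec = CohortSpec(
        n_samples=300,
        genes=tuple(
            [("G000", 0.3), ("G001", 0.3), ("G002", 0.3)]
            + [(f"G{i:03d}", 0.15) for i in range(3, 8)]
        ),
        drugs=("D00", "D01", "D02", "D03"),
        measures=("AUC", "EC50", "LFC"),
        seed=11,
    )
    truth = SyntheticTruth(
        snv_effects=(
            SnvEffect("G000", "D00", "EC50", 2.0, "sensitizing"),
            SnvEffect("G001", "D01", "AUC", 2.0, "resistant"),
            SnvEffect("G002", "D02", "LFC", 2.0, "sensitizing"),
        ),
        cnv_effects=(CnvEffect("G003", "D03", "AUC", 0.3),),
    )
    mut, cnv, resp, truth = generate_cohort(spec, truth)
    return {"spec": spec, "truth": truth, "mut": mut, "cnv": cnv,
            "resp": resp, "panel": panel_for_spec(spec)}
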