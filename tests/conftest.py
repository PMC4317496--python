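import numpy as np
import pytest

from amplistruct.genome import ChromosomePlan, FeaturePlan, ReferenceConfig, build_reference


@pytest.fixture(scope="session")
def small_genome():
    """60-kb single-chromosome diploid with a centromere and an identical LTR pair."""
    cfg = ReferenceConfig(
        chromosomes=(
            ChromosomePlan(
                name="chrA",
                length=60_000,
                features=(
                    FeaturePlan("centromere", 10_000, 10_120),
                    FeaturePlan("LTR", 20_000, 20_300, "+", family="delta", identity=1.0),
                    FeaturePlan("LTR", 40_000, 40_300, "+", family="delta", identity=1.0),
                ),
            ),
        ),
        seed=42,
    )
    return build_reference(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
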