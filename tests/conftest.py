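import pytest

from plantmir.pipeline import RunConfig, run_discovery
from plantmir.synth import SynthConfig, generate_genome


@pytest.fixture(scope="session")
def synth_clean():
    """Synthetic genome with 20 mismatch-free planted hairpins (seed 7)."""
    return generate_genome(SynthConfig(seed=7, per_arm_mismatches=0))


@pytest.fixture(scope="session")
def discovery_clean(synth_clean):
    """Full discovery run on the clean synthetic genome, decoys blocklisted."""
    return run_discovery(
        synth_clean.genome,
        synth_clean.references,
        synth_clean.genes,
        synth_clean.blocklist,
        RunConfig(engine="auto"),
    )
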