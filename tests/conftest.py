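import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssrhet.panel_io import GenotypePanel, IndividualMeta, MarkerDef
from ssrhet.synthetic import end_to_end_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _call(*alleles):
    return frozenset(alleles)


@pytest.fixture(scope="session")
def rare_allele_panel() -> GenotypePanel:
    """40 diploids at one locus: 39 homozygous A, 1 homozygous B.

    Copy-mode frequencies are 78/80 = 0.975 and 2/80 = 0.025, the spectrum
    behind the published RM175 diploid row.
    """
    markers = [MarkerDef("RM175", 3)]
    individuals = [IndividualMeta(f"ind{i:02d}", 2) for i in range(40)]
    calls = [[_call("A")] for _ in range(39)] + [[_call("B")]]
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


@pytest.fixture(scope="session")
def equifrequent_panel() -> GenotypePanel:
    """40 tetraploids, one biallelic locus at exactly 0.5/0.5."""
    markers = [MarkerDef("PSM416", 11)]
    individuals = [IndividualMeta(f"t{i:02d}", 4) for i in range(40)]
    calls = [[_call("A")] for _ in range(20)] + [[_call("B")] for _ in range(20)]
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


@pytest.fixture(scope="session")
def p65_panel() -> GenotypePanel:
    """40 diploids at one biallelic locus with frequencies 0.65 / 0.35."""
    markers = [MarkerDef("PSM429", 3)]
    individuals = [IndividualMeta(f"d{i:02d}", 2) for i in range(40)]
    calls = [[_call("A")] for _ in range(26)] + [[_call("B")] for _ in range(14)]
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


@pytest.fixture(scope="session")
def fixture_trio():
    """Deterministic small end-to-end fixture: (panel, crossplan, traits)."""
    return end_to_end_fixture(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
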