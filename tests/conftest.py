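import numpy as np
import pytest

from streammix import synthetic_data as sd


def zn_only_design(count_mode: str = "nb") -> sd.DesignConfig:
    """Single 6-level geometric Zn series with 4 control replicates."""
    return sd.DesignConfig(
        series=[sd.SeriesDef("Zn", ("Zn",), top_conc=1100.0)],
        kinetics={"Zn": sd.UptakeKinetics(1.0, 0.25, 1.3)},
        count_mode=count_mode,
    )


def single_mayfly_taxa(lambda0: float = 200.0, dispersion_k: float = 20.0,
                       ec50: float = 200.0, b: float = 4.0):
    return [
        sd.TaxonParams(
            "Mayfly pool", "Ephemeroptera/Baetidae", lambda0, dispersion_k,
            {"Zn": sd.MetalSensitivity(float(np.log10(ec50)), b)},
        )
    ]


@pytest.fixture(scope="session")
def noise_free_study():
    """Deterministic Zn/Cu/Cd study with a single shared mayfly sensitivity."""
    design = sd.default_design().without_noise()
    study, truth = sd.generate_experiment(sd.uniform_mayfly_taxa(), design, 1)
    return study, truth


@pytest.fixture(scope="session")
def default_noisy_study():
    study, truth = sd.generate_experiment(sd.default_taxa(), sd.default_design(), 11)
    return study, truth
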