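"""Shared fixtures: small hand-built models and the reference parameter sets."""

import pytest

from vegfrsim import (
    AdapterSpec,
    ModelParameters,
    ReceptorSpec,
    per_molar_rate_to_per_molecule,
    reference_parameters,
)


def make_mini_params(n_adapters: int = 2, kp_scale: float = 1.0) -> ModelParameters:
    """One receptor, two sites far enough apart for both adapters to co-bind."""
    receptor = ReceptorSpec(
        name="R1",
        concentration=5000.0,
        kon_vegf=per_molar_rate_to_per_molecule(1e7),
        koff_vegf=1e-3,
        sites=(("Y1", 1000), ("Y2", 1600)),  # 102.6 Å apart
        aa_spacing=0.171,
    )
    specs = [
        ("A1", 8e3, 1e6, 0.3, 40.0, ("Y1", "Y2"), {"migration": 0.6, "proliferation": 0.2}),
        ("A2", 3e3, 5e5, 0.5, 60.0, ("Y1", "Y2"), {"migration": 0.3, "proliferation": 0.7}),
        ("A3", 1e3, 8e5, 0.4, 50.0, ("Y2",), {"migration": 0.1, "proliferation": 0.1}),
    ]
    adapters = [
        AdapterSpec(
            name=name,
            concentration=conc,
            kon=per_molar_rate_to_per_molecule(kon_m),
            koff=koff,
            size_y=size,
            site_names={"R1": sites},
            weights=dict(weights),
            kp_scale=kp_scale,
        )
        for name, conc, kon_m, koff, size, sites, weights in specs[:n_adapters]
    ]
    return ModelParameters(receptors=[receptor], adapters=adapters).validate()


def make_shared_site_params() -> ModelParameters:
    """All adapters mapped to a single mutually exclusive site (reduction case)."""
    receptor = ReceptorSpec(
        name="R1",
        concentration=5000.0,
        kon_vegf=per_molar_rate_to_per_molecule(1e7),
        koff_vegf=1e-3,
        sites=(("Y1", 1000),),
    )
    adapters = [
        AdapterSpec("A1", 8e3, per_molar_rate_to_per_molecule(1e6), 0.3, 40.0,
                    {"R1": ("Y1",)}, {"migration": 0.6, "proliferation": 0.2}),
        AdapterSpec("A2", 3e3, per_molar_rate_to_per_molecule(5e5), 0.5, 60.0,
                    {"R1": ("Y1",)}, {"migration": 0.3, "proliferation": 0.7}),
    ]
    return ModelParameters(receptors=[receptor], adapters=adapters).validate()


@pytest.fixture
def mini_params() -> ModelParameters:
    return make_mini_params()


@pytest.fixture
def shared_site_params() -> ModelParameters:
    return make_shared_site_params()


@pytest.fixture(scope="session")
def huvec_params() -> ModelParameters:
    return reference_parameters("HUVEC")


@pytest.fixture(scope="session")
def raw_params() -> ModelParameters:
    return reference_parameters("RAW")
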