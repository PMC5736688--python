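"""Parameter model, unit conversions, file round-trips, fixture generation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegfrsim import (
    LigandSpec,
    ModelParameters,
    ParameterParseError,
    ParameterValidationError,
    ReceptorSpec,
    generate_fixture_parameters,
    ligand_molar,
    load_parameters,
    molar_to_molecules,
    molecules_to_molar,
    reference_parameters,
    save_parameters,
)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "molar, volume, expected",
        [
            (0.0, 1e-12, 0.0),
            (1e-9, 1e-12, 602.214076),  # 1 nM in a 1 pL cell
            (1.6605390671e-12, 1e-12, 1.0),  # one molecule per cell
        ],
    )
    def test_molar_to_molecules(self, molar, volume, expected):
        assert molar_to_molecules(molar, volume) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(min_value=1e-15, max_value=1e-3), st.floats(min_value=1e-15, max_value=1e-9))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, conc, volume):
        back = molecules_to_molar(molar_to_molecules(conc, volume), volume)
        assert abs(back - conc) / conc < 1e-12

    def test_negative_concentration_rejected(self):
        with pytest.raises(ParameterValidationError):
            molar_to_molecules(-1.0, 1e-12)

    @pytest.mark.parametrize(
        "mass, mw, expected_nm",
        [
            (0.0, 38200.0, 0.0),
            (50.0, 38200.0, 1.3089005),  # standard VEGF-A164 dose
            (38.2, 38200.0, 1.0),
        ],
    )
    def test_ligand_molar(self, mass, mw, expected_nm):
        lig = LigandSpec(concentration_mass=mass, molecular_weight=mw)
        assert ligand_molar(lig) * 1e9 == pytest.approx(expected_nm, rel=1e-6)

    def test_zero_molecular_weight_rejected(self):
        with pytest.raises(ParameterValidationError):
            ligand_molar(LigandSpec(concentration_mass=1.0, molecular_weight=0.0))


class TestValidation:
    def test_defaults(self):
        params = ModelParameters()
        assert params.kp == 0.01
        assert params.cell_volume == 1e-12

    def test_zero_adapters_is_legal(self, huvec_params):
        params = huvec_params.copy()
        params.adapters = []
        params.validate()

    def test_negative_adapter_concentration_rejected(self, mini_params):
        params = mini_params.copy()
        params.adapters[0].concentration = -5.0
        with pytest.raises(ParameterValidationError, match="concentration"):
            params.validate()

    def test_unknown_site_rejected(self, mini_params):
        params = mini_params.copy()
        params.adapters[0].site_names["R1"] = ("Y999",)
        with pytest.raises(ParameterValidationError, match="Y999"):
            params.validate()

    def test_nonincreasing_residues_rejected(self):
        rec = ReceptorSpec("R1", 100.0, 1e-5, 1e-3, sites=(("Ya", 500), ("Yb", 400)))
        with pytest.raises(ParameterValidationError, match="increasing"):
            rec.validate()

    def test_duplicate_adapter_names_rejected(self, mini_params):
        params = mini_params.copy()
        params.adapters[1].name = params.adapters[0].name
        with pytest.raises(ParameterValidationError, match="unique"):
            params.validate()


class TestFileRoundTrip:
    @pytest.mark.parametrize("cell", ["HUVEC", "RAW"])
    def test_reference_round_trip_exact(self, tmp_path, cell):
        params = reference_parameters(cell)
        save_parameters(params, tmp_path / "p")
        loaded = load_parameters(tmp_path / "p")
        assert dataclasses.asdict(loaded) == dataclasses.asdict(params)

    def test_fixture_round_trip_exact(self, tmp_path):
        params = generate_fixture_parameters(seed=11, n_adapters=4)
        save_parameters(params, tmp_path / "p")
        loaded = load_parameters(tmp_path / "p")
        assert dataclasses.asdict(loaded) == dataclasses.asdict(params)

    def test_missing_kp_defaults(self, tmp_path, mini_params):
        save_parameters(mini_params, tmp_path / "p")
        (tmp_path / "p" / "config.yaml").write_text("cell_volume: 1.0e-12\n")
        loaded = load_parameters(tmp_path / "p")
        assert loaded.kp == 0.01

    def test_missing_table_raises(self, tmp_path, mini_params):
        save_parameters(mini_params, tmp_path / "p")
        (tmp_path / "p" / "adapters.csv").unlink()
        with pytest.raises(ParameterParseError, match="adapters.csv"):
            load_parameters(tmp_path / "p")

    def test_malformed_field_names_line(self, tmp_path, mini_params):
        save_parameters(mini_params, tmp_path / "p")
        f = tmp_path / "p" / "adapters.csv"
        lines = f.read_text().splitlines()
        lines[1] = lines[1].replace(lines[1].split(",")[1], "not-a-number", 1)
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParameterParseError, match="line 2"):
            load_parameters(tmp_path / "p")

    def test_invalid_loaded_params_rejected(self, tmp_path, mini_params):
        params = mini_params.copy()
        params.adapters[0].concentration = -1.0
        save_parameters(params, tmp_path / "p")  # save does not validate
        with pytest.raises(ParameterValidationError, match="A1"):
            load_parameters(tmp_path / "p")


class TestFixtureGenerator:
    def test_deterministic_for_seed(self):
        a = generate_fixture_parameters(seed=1, n_adapters=5)
        b = generate_fixture_parameters(seed=1, n_adapters=5)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_seed_sensitivity(self):
        a = generate_fixture_parameters(seed=1, n_adapters=5)
        b = generate_fixture_parameters(seed=2, n_adapters=5)
        assert [x.concentration for x in a.adapters] != [x.concentration for x in b.adapters]

    def test_concentration_range(self):
        concs = np.array(
            [a.concentration
             for seed in range(200)
             for a in generate_fixture_parameters(seed=seed, n_adapters=5).adapters]
        )
        assert concs.min() >= 1e2 and concs.max() <= 1e5
        # log-uniform draws should span most of the range over 1000 samples
        assert concs.min() < 1e3 and concs.max() > 1e4

    def test_kd_range(self):
        for seed in range(20):
            params = generate_fixture_parameters(seed=seed, n_adapters=4)
            for a in params.adapters:
                kd_nm = molecules_to_molar(a.kd_molecules, params.cell_volume) * 1e9
                assert 1.0 <= kd_nm <= 1000.0 * (1 + 1e-9)

    def test_at_least_one_active_steric_constraint(self):
        for seed in range(10):
            params = generate_fixture_parameters(seed=seed, n_adapters=3)
            rec = params.receptors[0]
            # some two-adapter placement on adjacent sites must be blocked
            # purely by size (ignoring the site-map restriction)
            blocked = False
            names = rec.site_names
            for i in range(len(names) - 1):
                for a in params.adapters:
                    for b in params.adapters:
                        gap = (rec.residue(names[i + 1]) - rec.residue(names[i])) * rec.aa_spacing
                        if (a.size_y + b.size_y) / 2 >= gap:
                            blocked = True
            assert blocked

    def test_n_adapters_precondition(self):
        with pytest.raises(ParameterValidationError):
            generate_fixture_parameters(seed=1, n_adapters=0)
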