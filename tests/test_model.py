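"""Matrix assembly, pathology perturbations and the lumped-regime check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungident import (
    GROUND,
    CompartmentSet,
    DamperSpec,
    InvalidModelError,
    InvalidPerturbationError,
    PathologySpec,
    SpringSpec,
    ThoraxModel,
    TopologyError,
    apply_pathology,
    assemble_matrices,
    default_model,
    default_pathologies,
    wavelength_check,
)


def two_dof(k=1.0, ground=0.0):
    springs = [SpringSpec(0, 1, k)]
    if ground:
        springs.append(SpringSpec(0, GROUND, ground))
    return ThoraxModel(
        compartments=CompartmentSet(("a", "b")),
        masses=(1.0, 1.0),
        springs=tuple(springs),
        dampers=(DamperSpec(0, 1, 0.1),),
    )


class TestAssembly:
    def test_single_spring_two_dof(self):
        _, _, K = assemble_matrices(two_dof(k=1.0))
        np.testing.assert_array_equal(K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_partial_four_dof_assembly(self):
        """Only the two chest-lung couplings present: diagonal sums forced."""
        model = ThoraxModel(
            compartments=CompartmentSet(),
            masses=(1.0, 1.0, 1.0, 1.0),
            springs=(SpringSpec(0, 1, 240.0), SpringSpec(0, 2, 154.0)),
            dampers=(),
        )
        _, _, K = assemble_matrices(model)
        assert K[0, 0] == 394.0
        assert K[1, 1] == 240.0
        assert K[2, 2] == 154.0
        assert K[0, 1] == K[1, 0] == -240.0
        assert K[0, 2] == K[2, 0] == -154.0
        assert K[3, 3] == 0.0

    def test_empty_spring_list_gives_zero_matrix(self):
        model = ThoraxModel(
            compartments=CompartmentSet(("a", "b")),
            masses=(1.0, 2.0),
            springs=(),
            dampers=(),
        )
        M, C, K = assemble_matrices(model)
        np.testing.assert_array_equal(K, np.zeros((2, 2)))
        np.testing.assert_array_equal(C, np.zeros((2, 2)))
        np.testing.assert_array_equal(M, np.diag([1.0, 2.0]))

    def test_ground_spring_adds_diagonal_only(self):
        _, _, K = assemble_matrices(two_dof(k=1.0, ground=5.0))
        np.testing.assert_array_equal(K, [[6.0, -1.0], [-1.0, 1.0]])

    def test_row_sums_equal_ground_stiffness(self, model):
        """Internal forces balance: row sums reduce to the ground attachment."""
        _, C, K = assemble_matrices(model)
        ground = {s.endpoint_a: s.stiffness for s in model.springs if s.endpoint_b == GROUND}
        expected = np.array([ground.get(i, 0.0) for i in range(model.n_dof)])
        np.testing.assert_allclose(K.sum(axis=1), expected, atol=1e-12)

    def test_default_model_matrices_symmetric_and_psd(self, model):
        _, C, K = assemble_matrices(model)
        np.testing.assert_array_equal(K, K.T)
        np.testing.assert_array_equal(C, C.T)
        assert np.all(np.linalg.eigvalsh(K) > 0)  # grounded chain
        assert np.all(np.linalg.eigvalsh(C) >= -1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidModelError):
            ThoraxModel(
                compartments=CompartmentSet(("a",)),
                masses=(0.0,),
                springs=(),
                dampers=(),
            )

    def test_unknown_dof_rejected(self):
        with pytest.raises(TopologyError):
            ThoraxModel(
                compartments=CompartmentSet(("a", "b")),
                masses=(1.0, 1.0),
                springs=(SpringSpec(0, 5, 1.0),),
                dampers=(),
            )

    def test_duplicate_spring_pair_rejected(self):
        with pytest.raises(TopologyError):
            ThoraxModel(
                compartments=CompartmentSet(("a", "b")),
                masses=(1.0, 1.0),
                springs=(SpringSpec(0, 1, 1.0), SpringSpec(1, 0, 2.0)),
                dampers=(),
            )

    @given(
        ks=st.lists(
            st.floats(0.0, 1e3, allow_nan=False), min_size=6, max_size=6
        ),
        kg=st.floats(0.0, 1e3, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_stiffness_matrix_symmetric_psd_for_any_valid_model(self, ks, kg):
        names = ["k01", "k02", "k03", "k12", "k13", "k23"]
        model = default_model(stiffness={**dict(zip(names, ks)), "k0g": kg})
        _, C, K = assemble_matrices(model)
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(C, C.T)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-9 * max(1.0, np.abs(K).max())


class TestPathology:
    def test_healthy_is_identity(self, model):
        assert apply_pathology(model, PathologySpec("healthy")) == model

    def test_fibrosis_scales_k01(self, model):
        spec = default_pathologies(fibrosis_factor=1.5)["fibrosis_RU"]
        out = apply_pathology(model, spec)
        assert out.spring("k01").stiffness == pytest.approx(240.0 * 1.5)
        assert out.spring("k02").stiffness == model.spring("k02").stiffness

    def test_emphysema_softens(self, model):
        spec = PathologySpec("emphysema", stiffness_factors={"k02": 0.7})
        out = apply_pathology(model, spec)
        assert out.spring("k02").stiffness == pytest.approx(154.0 * 0.7)

    def test_dampers_never_altered(self, model):
        spec = PathologySpec("fibrosis_RU", stiffness_factors={"k01": 2.0})
        assert apply_pathology(model, spec).dampers == model.dampers

    def test_focal_mass_change(self, model):
        spec = PathologySpec("focal", stiffness_factors={"k01": 1.2}, mass_factors={1: 1.3})
        out = apply_pathology(model, spec)
        assert out.masses[1] == pytest.approx(model.masses[1] * 1.3)
        assert out.masses[0] == model.masses[0]

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InvalidPerturbationError):
            PathologySpec("fibrosis_RU", stiffness_factors={"k01": 0.0})

    def test_unknown_spring_rejected(self, model):
        with pytest.raises(TopologyError):
            apply_pathology(
                model, PathologySpec("fibrosis_RU", stiffness_factors={"k99": 1.5})
            )

    @given(
        a=st.floats(0.1, 5.0, allow_nan=False),
        b=st.floats(0.1, 5.0, allow_nan=False),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_multiplicative_composition(self, model, a, b):
        """Applying factor a then b equals applying a*b in one step."""
        one = apply_pathology(
            apply_pathology(model, PathologySpec("focal", stiffness_factors={"k01": a})),
            PathologySpec("focal", stiffness_factors={"k01": b}),
        )
        both = apply_pathology(
            model, PathologySpec("focal", stiffness_factors={"k01": a * b})
        )
        assert one.spring("k01").stiffness == pytest.approx(
            both.spring("k01").stiffness, rel=1e-12
        )


class TestWavelength:
    @pytest.mark.parametrize(
        "speed, freq, expected",
        [(20.0, 150.0, 0.13), (50.0, 150.0, 0.33)],
    )
    def test_band_edge_wavelengths(self, speed, freq, expected):
        assert round(wavelength_check(speed, freq), 2) == expected

    def test_ratio_identity(self):
        assert wavelength_check(42.0, 42.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("speed, freq", [(-1.0, 10.0), (10.0, 0.0)])
    def test_domain_errors(self, speed, freq):
        with pytest.raises(ValueError):
            wavelength_check(speed, freq)
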