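"""Core ODE right-hand side: invariants, boundaries, edge ablation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampktoggle.model import (
    InvalidParameterError,
    InvalidStateError,
    ModelParameters,
    ModelState,
    ModelVariant,
    TEMPLATE_VARIANT,
    default_parameters,
    rhs,
    rhs_vector,
    validate,
)

RATE_FIELDS = (
    "kaA", "kiA", "kiAU", "kiAM", "kamtor", "kiM", "kiMA", "kiMU",
    "kaUA", "kiU", "kiUM", "kaG0", "kaGU", "kiG", "kiGM",
)


class TestDefaults:
    def test_kamtor_is_half_the_hyperactivated_value(self, params):
        # hyper-activation doubles kamtor to 0.05, so baseline is 0.025
        assert params.kamtor == pytest.approx(0.025)

    def test_unit_totals(self, params):
        assert (params.AT, params.MT, params.UT, params.GT) == (1, 1, 1, 1)

    def test_no_basal_ulk1_activation(self, params):
        # ULK1 activation strictly requires AMPK: zero flux at A = 0
        d = rhs(ModelState(0.0, 0.0, 0.5, 0.0), params)
        assert d[2] < 0

    def test_defaults_valid(self, params):
        assert validate(params) == []

    def test_residual_autophagy_is_small(self, params):
        assert 0 < params.kaG0 < 0.1 * params.kaGU * params.UT


class TestValidate:
    @pytest.mark.parametrize(
        "field,value",
        [("JaA", 0.0), ("JiG", -1.0), ("UT", -0.1), ("kaA", -0.5),
         ("kiM", float("nan"))],
    )
    def test_violation_names_offending_field(self, params, field, value):
        bad = params.replace(**{field: value})
        violations = validate(bad)
        assert len(violations) == 1
        assert field in violations[0]

    def test_unknown_field_rejected(self, params):
        with pytest.raises(InvalidParameterError, match="kfoo"):
            params.replace(kfoo=1.0)
        with pytest.raises(InvalidParameterError):
            ModelParameters.from_dict({**params.to_dict(), "typo": 2.0})


class TestRhs:
    def test_all_zero_rates_gives_zero_flux(self):
        p = ModelParameters(**{f: 0.0 for f in RATE_FIELDS})
        d = rhs(ModelState(0.0, 0.0, 0.0, 0.0), p)
        assert np.all(d == 0.0)

    def test_activation_flux_vanishes_at_the_total(self, params):
        d = rhs(ModelState(0.2, 0.3, params.UT, 0.1), params)
        assert d[2] <= 0.0  # only inactivation remains at U = UT

    def test_rest_state_is_an_rhs_root(self, params, rest_state):
        d = rhs(rest_state, params)
        assert np.max(np.abs(d)) < 1e-9

    def test_invalid_state_raises(self, params):
        with pytest.raises(InvalidStateError):
            rhs(ModelState(1.5, 0.0, 0.0, 0.0), params)

    def test_invalid_michaelis_raises(self, params):
        with pytest.raises(InvalidParameterError):
            rhs(ModelState(0.1, 0.1, 0.1, 0.1), params.replace(JiA=0.0))


states = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4
)
rates = st.floats(min_value=0.0, max_value=1.0)


class TestProperties:
    @settings(max_examples=50, deadline=None)
    @given(y=states)
    def test_boundary_flux_never_leaves_the_box(self, y):
        """On any box face the derivative points inward or along it."""
        p = default_parameters()
        v = ModelVariant()
        y = np.asarray(y)
        d = rhs_vector(y, p, v)
        for j, total in enumerate([p.AT, p.MT, p.UT, p.GT]):
            if y[j] == 0.0:
                assert d[j] >= 0.0
            if y[j] == total:
                assert d[j] <= 0.0

    @settings(max_examples=30, deadline=None)
    @given(y=states, s=rates)
    def test_edge_switch_equals_zero_coefficient(self, y, s):
        """Ablating an edge by switch is bitwise-identical to zeroing it."""
        p = default_parameters().replace(S=max(s, 1e-3))
        y = np.asarray(y)
        pairs = [
            ("mtor_inhibits_ampk", "kiAM"),
            ("ulk1_inhibits_ampk", "kiAU"),
            ("ampk_activates_ulk1", "kaUA"),
            ("mtor_inhibits_ulk1", "kiUM"),
            ("ulk1_inhibits_mtor", "kiMU"),
            ("ampk_inhibits_mtor", "kiMA"),
            ("mtor_inhibits_atg", "kiGM"),
            ("ulk1_activates_atg", "kaGU"),
        ]
        for switch, coeff in pairs:
            by_switch = rhs_vector(y, p, ModelVariant(**{switch: False}))
            by_zero = rhs_vector(y, p.replace(**{coeff: 0.0}), ModelVariant())
            assert np.array_equal(by_switch, by_zero)

    @settings(max_examples=30, deadline=None)
    @given(y=states)
    def test_template_variant_is_exactly_the_kiAM_zero_model(self, y):
        p = default_parameters()
        y = np.asarray(y)
        a = rhs_vector(y, p, TEMPLATE_VARIANT)
        b = rhs_vector(y, p.replace(kiAM=0.0), ModelVariant())
        assert np.array_equal(a, b)

    @settings(max_examples=50, deadline=None)
    @given(y=states)
    def test_derivatives_finite_everywhere_in_the_box(self, y):
        p = default_parameters()
        assert np.all(np.isfinite(rhs_vector(np.asarray(y), p, ModelVariant())))


class TestSerialization:
    def test_round_trip_dict(self, params):
        assert ModelParameters.from_dict(params.to_dict()) == params

    def test_variant_round_trip(self, template):
        assert ModelVariant.from_dict(template.to_dict()) == template

    def test_variant_unknown_key_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelVariant.from_dict({"mtor_inhibits_ampk": True, "oops": 1})
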