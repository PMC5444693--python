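"""Dose/mutation semantics, regime validation, and locality properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathdyn import (
    Intervention,
    Regime,
    apply_intervention,
    load_regime,
    make_dose,
    save_regime,
    simulate,
    validate_regime,
)
from pathdyn.errors import IntegrityError, UnknownTargetError, ValidationError

SPECIES = {"A": 0, "B": 1, "PTEN": 2}
PARAMS = {"k1": 0, "k2": 1}


def _apply(conc, pars, iv):
    return apply_intervention(np.asarray(conc, float), np.asarray(pars, float),
                              iv, SPECIES, PARAMS)


@pytest.mark.parametrize(
    "iv, conc_after, pars_after",
    [
        # a 30 nM bolus adds to the drug species, everything else untouched
        (Intervention("dose", "A", 30.0), [30.0, 5.0, 8.0], [1.0, 2.0]),
        (Intervention("set_concentration", "B", 1.5), [0.0, 1.5, 8.0], [1.0, 2.0]),
        # the 50%-reduction mutation pattern
        (Intervention("scale_concentration", "PTEN", 0.5), [0.0, 5.0, 4.0], [1.0, 2.0]),
        (Intervention("set_parameter", "k2", 9.0), [0.0, 5.0, 8.0], [1.0, 9.0]),
        (Intervention("scale_parameter", "k1", 1.0), [0.0, 5.0, 8.0], [1.0, 2.0]),
    ],
)
def test_apply_intervention_semantics(iv, conc_after, pars_after):
    conc, pars = _apply([0.0, 5.0, 8.0], [1.0, 2.0], iv)
    assert conc.tolist() == conc_after
    assert pars.tolist() == pars_after


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    kind=st.sampled_from(["dose", "set_concentration", "scale_concentration",
                          "set_parameter", "scale_parameter"]),
    target_i=st.integers(0, 2),
    value=st.floats(0.0, 100.0, allow_nan=False),
    state=st.lists(st.floats(0.0, 50.0, allow_nan=False), min_size=3, max_size=3),
)
def test_apply_intervention_touches_exactly_one_entry(kind, target_i, value, state):
    """Locality: one entry of one vector changes; all others are identical."""
    names = list(SPECIES) if kind in ("dose", "set_concentration",
                                      "scale_concentration") else list(PARAMS)
    target = names[target_i % len(names)]
    iv = Intervention(kind, target, value)
    conc0, pars0 = np.array(state), np.array([1.0, 2.0])
    conc, pars = apply_intervention(conc0, pars0, iv, SPECIES, PARAMS)
    changed = int(np.sum(conc != conc0)) + int(np.sum(pars != pars0))
    assert changed <= 1  # 0 when the new value coincides with the old


def test_scale_composition_multiplies_factors():
    a, b = 0.5, 0.3
    iv_a = Intervention("scale_concentration", "PTEN", a)
    iv_b = Intervention("scale_concentration", "PTEN", b)
    conc, pars = _apply(*_apply([1, 1, 8.0], [1, 2], iv_a), iv_b)
    conc2, _ = _apply([1, 1, 8.0], [1, 2],
                      Intervention("scale_concentration", "PTEN", a * b))
    assert conc[2] == pytest.approx(conc2[2])


def test_invalid_interventions_rejected():
    with pytest.raises(ValidationError):
        Intervention("dose", "A", -1.0)
    with pytest.raises(ValidationError):
        Intervention("dose", "A", 1.0, time=-0.1)
    with pytest.raises(ValidationError):
        Intervention("teleport", "A", 1.0)
    with pytest.raises(UnknownTargetError):
        _apply([0, 0, 0], [1, 2], Intervention("dose", "NOPE", 1.0))


class TestMakeDose:
    def test_paper_patterned_doses(self, receptor_catalogue):
        iv = make_dose(receptor_catalogue, "inhibitor", 30.0, time=0.0)
        assert (iv.kind, iv.target, iv.value, iv.time) == ("dose", "I", 30.0, 0.0)

    def test_omitted_dosage_uses_catalogue_default(self, receptor_catalogue):
        iv = make_dose(receptor_catalogue, "inhibitor")
        assert iv.value == receptor_catalogue.get("inhibitor").default_dosage

    def test_unknown_drug_and_negative_dosage(self, receptor_catalogue):
        with pytest.raises(UnknownTargetError):
            make_dose(receptor_catalogue, "no-such-drug")
        with pytest.raises(ValidationError):
            make_dose(receptor_catalogue, "inhibitor", -5.0)


class TestValidateRegime:
    def test_sorts_by_time_stably(self, receptor_fx):
        ivs = [
            Intervention("dose", "I", 1.0, 5.0),
            Intervention("dose", "I", 2.0, 1.0),
            Intervention("dose", "I", 3.0, 5.0),
        ]
        out = validate_regime(Regime("R", ivs), receptor_fx.network, 10.0)
        assert [iv.value for iv in out.interventions] == [2.0, 1.0, 3.0]

    def test_empty_regime_is_the_valid_control(self, receptor_fx):
        out = validate_regime(Regime("Control"), receptor_fx.network, 10.0)
        assert out.is_empty

    def test_rejects_unknown_target_and_out_of_range_time(self, receptor_fx):
        with pytest.raises(IntegrityError):
            validate_regime(
                Regime("R", [Intervention("dose", "GHOST", 1.0)]),
                receptor_fx.network, 10.0,
            )
        with pytest.raises(ValidationError):
            validate_regime(
                Regime("R", [Intervention("dose", "I", 1.0, 20.0)]),
                receptor_fx.network, 10.0,
            )


def test_identity_interventions_equal_empty_regime(receptor_fx):
    """Scale-by-1 interventions leave the trajectory exactly unchanged."""
    identity = Regime("Identity", [
        Intervention("scale_concentration", "R2", 1.0, 2.0),
        Intervention("scale_parameter", "k_dim", 1.0, 4.0),
    ])
    a = simulate(receptor_fx.network, Regime("Control"), t_end=6.0, n_points=61)
    b = simulate(receptor_fx.network, identity, t_end=6.0, n_points=61)
    assert np.array_equal(a.concentrations, b.concentrations)
    assert np.array_equal(a.velocities, b.velocities)


def test_regime_yaml_round_trip(tmp_path, receptor_catalogue):
    regime = Regime("Experiment", [
        Intervention("dose", "I", 30.0, 0.0),
        Intervention("scale_concentration", "R3", 0.5, 0.0),
    ])
    path = save_regime(regime, tmp_path / "regime.yaml")
    reread = load_regime(path)
    assert reread.label == "Experiment"
    assert reread.interventions == regime.interventions


def test_regime_file_resolves_drug_names(tmp_path, receptor_catalogue):
    p = tmp_path / "r.yaml"
    p.write_text(
        "label: Experiment\n"
        "interventions:\n"
        "  - {kind: dose, drug: inhibitor, time: 0}\n"
    )
    regime = load_regime(p, receptor_catalogue)
    assert regime.interventions[0].target == "I"
    assert regime.interventions[0].value == 30.0
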