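"""Built-in example models.

Seven ready-made models used throughout the documentation and tests:

* ``m1`` — two-state uncontrolled benchmark with a zero-valued problematic
  initial condition (``x2(0) = 0`` makes ``p2, p3`` totally correlated).
* ``m1_reparam`` — its identifiable reparameterisation (``phi = p2*p3`` with
  the second state scaled by ``p3``).
* ``m2`` — two-state benchmark with one input signal; the problematic
  initial condition ``x2(0) = p1/p3`` is nonzero and parameter-tied.
* ``m3_epo`` — six-state erythropoietin (Epo) / Epo-receptor interaction and
  trafficking model with two scaled outputs and unknown ``[Epo](0)``,
  ``[EpoR](0)``; 10 unknowns in total.
* ``m4_jakstat`` — fourteen-state JAK/STAT signalling model with 22 system
  and output parameters plus unknown ``x2(0)``: 23 unknowns.
* ``m5_pk`` — four-state pharmacokinetics model of ligand binding to the
  macrophage mannose receptor; globally identifiable generically, but not on
  thin initial-condition sets such as ``x3(0) = x4(0) = 0``.
* ``toy_eq48`` — one-state cautionary model ``dx/dt = 1 + theta1*x^2``,
  ``x(0) = 0``, which some purely symbolic methods misclassify; the numeric
  screening correctly finds it identifiable.

Each fixture comes with a default scenario: the published initial-condition
pattern plus a seeded nominal assignment (free values drawn log-uniform from
[0.1, 10]).
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from .ic_search import IcPattern, draw_loguniform
from .model_core import (NominalAssignment, OdeModel,
                         promote_initial_conditions, validate_model)

__all__ = ["FIXTURE_IDS", "build_fixture", "default_scenario", "default_config"]

FIXTURE_IDS = ("m1", "m1_reparam", "m2", "m3_epo", "m4_jakstat", "m5_pk",
               "toy_eq48")


def _syms(names: str):
    return sp.symbols(names, seq=True)


def _m1() -> OdeModel:
    x1, x2, p1, p2, p3, x10 = _syms("x1 x2 p1 p2 p3 x10")
    return OdeModel(
        name="m1",
        states=(x1, x2), params=(p1, p2, p3),
        drift=(p1 * x1**2 + p2 * x1 * x2, p3 * x1**2 + x1 * x2),
        outputs=(x1,),
        initial_conditions=(x10, sp.S.Zero),
    )


def _m1_reparam() -> OdeModel:
    x1, x2t, p1, phi, x10 = _syms("x1 x2t p1 phi x10")
    return OdeModel(
        name="m1_reparam",
        states=(x1, x2t), params=(p1, phi),
        drift=(p1 * x1**2 + phi * x1 * x2t, x1**2 + x1 * x2t),
        outputs=(x1,),
        initial_conditions=(x10, sp.S.Zero),
    )


def _m2() -> OdeModel:
    x1, x2, p0, p1, p2, p3, x10, u1 = _syms("x1 x2 p0 p1 p2 p3 x10 u1")
    return OdeModel(
        name="m2",
        states=(x1, x2), params=(p0, p1, p2, p3),
        drift=(-p2 * x1 - p3 * x2, p3 * x1 * x2 - p1 * x1),
        inputs=(u1,),
        input_fields=((-p0, sp.S.Zero),),
        outputs=(x1,),
        initial_conditions=(x10, p1 / p3),
    )


def _m3_epo() -> OdeModel:
    Epo, EpoR, EE, EEi, dEi, dEe = _syms("Epo EpoR Epo_EpoR Epo_EpoR_i dEpo_i dEpo_e")
    k_on, k_D, k_ex, k_t, k_e, k_di, k_de, scale = _syms(
        "k_on k_D k_ex k_t k_e k_di k_de scale")
    Epo0, EpoR0 = _syms("Epo0 EpoR0")
    binding = -k_on * Epo * EpoR + k_on * k_D * EE
    model = OdeModel(
        name="m3_epo",
        states=(Epo, EpoR, EE, EEi, dEi, dEe),
        params=(k_on, k_D, k_ex, k_t, k_e, k_di, k_de, scale),
        drift=(
            binding + k_ex * EEi,
            binding + k_t * EpoR0 - k_t * EpoR + k_ex * EEi,
            -binding - k_e * EE,
            k_e * EE - k_ex * EEi - k_di * EEi - k_de * EEi,
            k_di * EEi,
            k_de * EEi,
        ),
        outputs=(scale * (Epo + dEe), scale * EE),
        initial_conditions=(Epo0, EpoR0, sp.S.Zero, sp.S.Zero, sp.S.Zero,
                            sp.S.Zero),
    )
    return promote_initial_conditions(model, {"Epo", "EpoR"})


def _m4_jakstat() -> OdeModel:
    x = _syms(" ".join(f"x{i}" for i in range(1, 15)))
    th = _syms(" ".join(f"theta{i}" for i in range(1, 23)))
    c1, c2 = _syms("c1 c2")
    u1 = sp.Symbol("u1")
    (x1, x2, x3, x4, x5, x6, x7, x8, x9, x10_, x11, x12, x13, x14) = x
    hill = 1 + th[12] * x13
    drift = (
        -th[4] * x1 + th[5] * x2,
        th[4] * x1 - th[5] * x2,
        -th[1] * x3 * x7,
        th[1] * x3 * x7 - th[2] * x4,
        th[2] * x4 - th[3] * x5,
        -th[6] * x3 * x6 / hill - th[6] * x4 * x6 / hill + th[7] * c2 * x7,
        th[6] * x3 * x6 / hill + th[6] * x4 * x6 / hill - th[7] * c2 * x7,
        -th[8] * x8 * x7 + c2 * th[9] * x9,
        th[8] * x8 * x7 - c2 * th[9] * x9,
        th[10] * x9,
        sp.S.Zero,
        sp.S.Zero,
        th[13] * x10_ / (th[14] + x10_) - th[15] * x13,
        th[16] * x9,
    )
    input_field = (
        -th[0] * c1 * x1, sp.S.Zero, th[0] * c1 * x1, sp.S.Zero, sp.S.Zero,
        sp.S.Zero, sp.S.Zero, sp.S.Zero, sp.S.Zero, sp.S.Zero,
        -th[11] * c1 * x11, th[11] * c1 * x11, sp.S.Zero, sp.S.Zero,
    )
    outputs = (
        x1 + x3 + x4,
        th[17] * (x3 + x4 + x5 + x12),
        th[18] * (x4 + x5),
        th[19] * x7,
        th[20] * x10_,
        th[21] * x14,
        x13,
        x9,
    )
    x2_0 = sp.Symbol("x2_0")
    ics = (sp.Rational("1.3"), x2_0, sp.S.Zero, sp.S.Zero, sp.S.Zero,
           sp.Rational("2.8"), sp.S.Zero, sp.Integer(165), sp.S.Zero,
           sp.S.Zero, sp.Rational("0.34"), sp.S.Zero, sp.S.Zero, sp.S.Zero)
    model = OdeModel(
        name="m4_jakstat",
        states=x, params=th, drift=drift,
        inputs=(u1,), input_fields=(input_field,),
        outputs=outputs, initial_conditions=ics,
        constants=((c1, 1.0), (c2, 1.0)),
    )
    return promote_initial_conditions(model, {"x2"})


def _m5_pk() -> OdeModel:
    x1, x2, x3, x4 = _syms("x1 x2 x3 x4")
    a1, a2, ka, Vm, kc, b1, b2 = _syms("alpha1 alpha2 ka Vm kc beta1 beta2")
    den = kc * ka + kc * x3 + ka * x1
    model = OdeModel(
        name="m5_pk",
        states=(x1, x2, x3, x4),
        params=(a1, a2, ka, Vm, kc, b1, b2),
        drift=(
            a1 * (x2 - x1) - ka * Vm * x1 / den,
            a2 * (x1 - x2),
            b1 * (x4 - x3) - kc * Vm * x3 / den,
            b2 * (x3 - x4),
        ),
        outputs=(x1,),
        initial_conditions=(sp.Symbol("x1_0"), sp.Symbol("x2_0"),
                            sp.Symbol("x3_0"), sp.Symbol("x4_0")),
    )
    return promote_initial_conditions(model, {"x1", "x2", "x3", "x4"})


def _toy_eq48() -> OdeModel:
    x1, th1 = _syms("x1 theta1")
    return OdeModel(
        name="toy_eq48",
        states=(x1,), params=(th1,),
        drift=(1 + th1 * x1**2,),
        outputs=(x1,),
        initial_conditions=(sp.S.Zero,),
    )


_BUILDERS = {
    "m1": _m1, "m1_reparam": _m1_reparam, "m2": _m2, "m3_epo": _m3_epo,
    "m4_jakstat": _m4_jakstat, "m5_pk": _m5_pk, "toy_eq48": _toy_eq48,
}


def build_fixture(fixture_id: str) -> OdeModel:
    """Build a fixture model (already promoted to its default unknown set).

    Unknown counts: m1 (3), m1_reparam (2), m2 (4), m3_epo (10),
    m4_jakstat (23), m5_pk (11), toy_eq48 (1).
    """
    try:
        builder = _BUILDERS[fixture_id]
    except KeyError:
        raise ValueError(f"unknown fixture id {fixture_id!r}; "
                         f"choose from {FIXTURE_IDS}") from None
    model = builder()
    diags = validate_model(model)
    assert not diags, f"fixture {fixture_id} failed validation: {diags}"
    return model


def default_scenario(fixture_id: str, seed: int = 0):
    """Published initial-condition pattern, seeded nominal assignment, and
    output selection for a fixture.

    Free nominal values are drawn log-uniform from [0.1, 10] with the given
    seed (recorded in the assignment); initial values forced to zero by the
    pattern get nominal value zero.
    """
    model = build_fixture(fixture_id)
    rng = np.random.default_rng(seed)

    patterns = {
        "m1": {"x1": ("generic",), "x2": ("zero",)},
        "m1_reparam": {"x1": ("generic",), "x2t": ("zero",)},
        "m2": {"x1": ("generic",)},          # x2(0) = p1/p3 from the model
        "m3_epo": {},                        # unknown Epo(0), EpoR(0); rest zero
        "m4_jakstat": {},                    # printed numeric values; x2(0) unknown
        "m5_pk": {"x3": ("zero",), "x4": ("zero",)},
        "toy_eq48": {"x1": ("zero",)},
    }
    pattern = IcPattern.from_map(model, patterns[fixture_id],
                                 label=f"{fixture_id} default")

    values = {}
    zero_syms = set()
    promoted = set(model.ic_params)
    for x, ic, e in zip(model.states, model.initial_conditions, pattern.entries):
        if e[0] == "zero" and ic.is_Symbol and ic in promoted:
            zero_syms.add(ic)
    for s in model.unknowns:
        values[s] = 0.0 if s in zero_syms else float(draw_loguniform(rng))
    nominal = NominalAssignment.from_dict(values, provenance="seeded-random",
                                          seed=seed)
    return nominal, pattern, tuple(range(model.m))


def default_config(fixture_id: str, **overrides):
    """Default experiment configuration for a fixture.

    Controlled fixtures need persistently exciting inputs: for ``m2`` the
    constant signal leaves ``x2`` frozen at its parameter-tied initial value,
    which makes ``p0`` and ``p1`` genuinely inseparable on top of the
    structural ``p3`` defect, so its default input is ``u = 1 + sin t +
    0.5 sin 3t``.  The ``m4_jakstat`` stimulus is the constant 1.
    """
    from .sensitivity import ExperimentConfig

    if fixture_id not in _BUILDERS:
        raise ValueError(f"unknown fixture id {fixture_id!r}")
    kw: dict = {}
    if fixture_id == "m2":
        kw["input_signals"] = (("sines", (1.0, 0.5), (1.0, 3.0), 1.0),)
    elif fixture_id == "m4_jakstat":
        kw["input_signals"] = (("constant", 1.0),)
    kw.update(overrides)
    return ExperimentConfig(**kw)
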