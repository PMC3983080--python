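"""A miniature three-member bank of stimulus-driven phosphorylation cascades.

All members describe the same physiology at different levels of abstraction:
a receptor-proximal signal, switched on by a unit stimulus step at t = 0 and
desensitizing over tens of minutes, drives a three-tier kinase cascade whose
terminal phosphoprotein is the controlled output (a pErk analogue).  Two
reagents manipulate the terminal tier through saturating Hill terms:

* input 1 (range [0, 50] uM) inhibits the terminal *phosphatase* — moderate
  to high doses elevate and sustain the output;
* input 2 (range [0, 10] uM) inhibits the terminal *kinase* — even low doses
  cut the phosphorylation rate immediately, and at high doses this effect
  overpowers simultaneous phosphatase inhibition.

The members are structurally distinct:

* ``cascade_ma``   — pure mass-action, explicit phospho/unphospho pairs per
  tier (tier totals are conserved by construction);
* ``cascade_fb``   — mass-action with an output-driven negative feedback on
  receptor desensitization and a positive feedback on tier-2 activation;
* ``cascade_hill`` — normalized Hill-type dynamics with states on [0, 1]
  (the continuous homologue of a logical-model description).

Rate constants are fixed documented constants — part of the repository's
fixture contract, not fitted to anything.
"""

from __future__ import annotations

import numpy as np

from .model_bank import PredictionModel, calibrate_normalization

__all__ = ["make_toy_bank", "HILL_INPUT_PARAMS"]

#: Saturating input-effect parameters: phi1/phi2 are the residual activity
#: factors of the terminal phosphatase/kinase, phi = 1 - Imax * u / (u + K).
#: Each member carries its own input coupling — the members agree closely on
#: the uncontrolled stimulation response (all were "calibrated" to the same
#: biology and are normalized to unit peak) but disagree on how strongly the
#: two reagents act, which is exactly the kind of plant-model mismatch the
#: weight maps are meant to resolve.
HILL_INPUT_PARAMS = dict(
    cascade_ma=dict(I1max=0.85, K1=5.0, I2max=0.95, K2=3.0),
    cascade_fb=dict(I1max=0.88, K1=7.0, I2max=0.99, K2=0.6),
    cascade_hill=dict(I1max=0.85, K1=6.0, I2max=0.98, K2=1.2),
)


def _phi1(u1: float, p: dict) -> float:
    return 1.0 - p["I1max"] * u1 / (u1 + p["K1"])


def _phi2(u2: float, p: dict) -> float:
    return 1.0 - p["I2max"] * u2 / (u2 + p["K2"])


# ---------------------------------------------------------------- member A

MA_PARAMS = dict(
    kd=0.22,   # /min receptor desensitization
    Rss=0.04,  # residual receptor signal plateau
    k1=2.0,    # /min tier-1 phosphorylation gain
    d1=0.7,    # /min tier-1 dephosphorylation
    k2=1.0,
    d2=0.7,
    k3=1.2,
    d3=0.8,
    **HILL_INPUT_PARAMS["cascade_ma"],
)


def _ma_rhs(x, u, t, p):
    R, p1, q1, p2, q2, p3, q3 = x
    f1 = _phi1(u[0], p)
    f2 = _phi2(u[1], p)
    v1 = p["k1"] * R * q1 - p["d1"] * p1
    v2 = p["k2"] * p1 * q2 - p["d2"] * p2
    v3 = p["k3"] * f2 * p2 * q3 - p["d3"] * f1 * p3
    return np.array([-p["kd"] * (R - p["Rss"]), v1, -v1, v2, -v2, v3, -v3])


# ---------------------------------------------------------------- member B

# constants calibrated so the uncontrolled response matches the bank's
# common stimulation phenotype (shared "training biology"); feedback loops
# retained as structural features
FB_PARAMS = dict(
    kd=0.2148,  # baseline desensitization
    Rss=0.0379,  # residual receptor signal plateau
    kn=0.30,    # negative feedback: output accelerates desensitization
    k1=1.5633,
    d1=0.3542,
    k2=1.5789,
    kp=1.0128,  # positive feedback: output boosts tier-2 activation
    d2=0.8363,
    k3=0.20,
    d3=1.2799,
    **HILL_INPUT_PARAMS["cascade_fb"],
)


def _fb_rhs(x, u, t, p):
    R, p1, p2, p3 = x
    f1 = _phi1(u[0], p)
    f2 = _phi2(u[1], p)
    dR = -(p["kd"] + p["kn"] * p3) * (R - p["Rss"])
    dp1 = p["k1"] * R * (1 - p1) - p["d1"] * p1
    dp2 = p["k2"] * (1 + p["kp"] * p3) * p1 * (1 - p2) - p["d2"] * p2
    dp3 = p["k3"] * f2 * p2 * (1 - p3) - p["d3"] * f1 * p3
    return np.array([dR, dp1, dp2, dp3])


# ---------------------------------------------------------------- member C

# constants calibrated to the same uncontrolled phenotype as the other
# members (normalized Hill structure retained)
HILL_PARAMS = dict(
    tau_a=6.4067,  # min, receptor adaptation
    a_ss=0.6647,   # adaptation plateau: drive settles at 1 - a_ss
    tau1=0.50,
    Ka=0.70,
    tau2=0.50,
    Kb=0.4718,
    tau3=2.1453,
    Kc=0.70,
    kdeg=1.50,
    **HILL_INPUT_PARAMS["cascade_hill"],
)

_HILL_N = 2  # structural Hill exponent, fixed


def _nhill(v, K):
    """Normalized Hill function: h(1) = 1."""
    vn = max(v, 0.0) ** _HILL_N
    return vn / (vn + K**_HILL_N) * (1 + K**_HILL_N)


def _hill_rhs(x, u, t, p):
    a, x1, x2, x3 = x
    f1 = _phi1(u[0], p)
    f2 = _phi2(u[1], p)
    drive = max(1.0 - a, 0.0)
    da = (p["a_ss"] - a) / p["tau_a"]
    dx1 = (_nhill(drive, p["Ka"]) - x1) / p["tau1"]
    dx2 = (_nhill(x1, p["Kb"]) - x2) / p["tau2"]
    dx3 = (f2 * _nhill(x2, p["Kc"]) * (1 - x3) - p["kdeg"] * f1 * x3) / p["tau3"]
    return np.array([da, dx1, dx2, dx3])


# --------------------------------------------------------------- assembly


def _last_state_output(idx):
    def h(x, u, t, params):
        return np.array([x[idx]])

    return h


def make_toy_bank(seed: int = 0):
    """Build the calibrated three-member bank and the designated plant.

    Returns ``(models, plant)`` where ``models`` is a list of three
    calibrated :class:`PredictionModel` members and ``plant`` is an
    independent copy of the Hill-type member.  Rate constants are fixed
    (``seed`` is accepted for interface stability but does not alter them).
    """
    del seed
    ma = PredictionModel(
        model_id="cascade_ma",
        n_x=7,
        n_u=2,
        x0=np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
        params=dict(MA_PARAMS),
        rhs=_ma_rhs,
        measured_map=_last_state_output(5),
        controlled_map=_last_state_output(5),
        n_params=4,
    )
    fb = PredictionModel(
        model_id="cascade_fb",
        n_x=4,
        n_u=2,
        x0=np.array([1.0, 0.0, 0.0, 0.0]),
        params=dict(FB_PARAMS),
        rhs=_fb_rhs,
        measured_map=_last_state_output(3),
        controlled_map=_last_state_output(3),
        n_params=4,
    )
    hill = PredictionModel(
        model_id="cascade_hill",
        n_x=4,
        n_u=2,
        x0=np.array([0.0, 0.0, 0.0, 0.0]),
        params=dict(HILL_PARAMS),
        rhs=_hill_rhs,
        measured_map=_last_state_output(3),
        controlled_map=_last_state_output(3),
        n_params=4,
    )
    models = [calibrate_normalization(m) for m in (ma, fb, hill)]
    plant = models[2].copy()
    return models, plant
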