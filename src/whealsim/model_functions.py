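"""Closed-form response functions of the CSU wheal-formation network.

The hierarchical model couples four concentration variables — histamine
released from basophils ``[H_B]``, tissue-factor expression on vascular
endothelium ``[TF]``, coagulation factors leaked from blood vessels ``[C]``
and histamine released from dermal mast cells ``[H_M]`` — through a small
set of saturating response functions calibrated from in vitro dose–response
data:

* adenosine-mediated inhibition of histamine release (Hill curves with
  exponent 2),
* histamine-driven tissue-factor activation (saturating, exponent 1),
* a sigmoidal plasma-leakage switch gated by the TF concentration, and
* a sigmoidal eruption-state map from dermal concentration to visible wheal
  occupancy on the skin.

All functions here are pure and stateless; they accept scalars or numpy
arrays and evaluate elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ResponseParams",
    "eruption_state",
    "hill_inhibition",
    "tf_activation",
    "leakage_rate",
]

# exp() overflows float64 near 709; clamping preserves 0/1 saturation.
_EXP_CLAMP = 700.0


def _checked(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _checked_nonneg(x, name: str):
    arr = _checked(x, name)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))


@dataclass
class ResponseParams:
    """Parameters of the calibrated response functions.

    The defaults are a documented calibration surrogate: the half-saturation
    constants are placed inside the concentration range explored by the
    synthetic-data generators, and the leakage switch threshold ``t_sw``
    sits at 2 ng/mL, the midpoint of the experimentally bracketed 1–3 ng/mL
    transition of endothelial gap formation. All values are overridable from
    the run configuration.

    Attributes
    ----------
    alpha_b, alpha_b0:
        Maximal inhibition ratio and squared half-saturation constant of
        adenosine inhibition of basophil histamine release (Hill-2).
    alpha_m, alpha_m0:
        Same for mast-cell histamine release.
    alpha_t, alpha_t0:
        Same for tissue-factor expression; the argument is the summed
        histamine concentration ``[H_B] + [H_M]``.
    gamma_t, gamma_t0:
        Maximal rate and half-saturation constant of histamine-driven TF
        activation (saturating, exponent 1).
    gamma_c:
        Plasma-leakage rate of coagulation factors (concentration/time).
    beta:
        Steepness of the TF leakage switch (per ng/mL).
    t_sw:
        TF threshold of the leakage switch (ng/mL).
    beta_w:
        Steepness of the eruption-state sigmoid.
    a_r:
        Dermal concentration threshold at which the eruption becomes
        visible on the skin.
    """

    alpha_b: float = 0.9
    alpha_b0: float = 25.0
    alpha_m: float = 0.9
    alpha_m0: float = 25.0
    alpha_t: float = 0.8
    alpha_t0: float = 100.0
    gamma_t: float = 2.0
    gamma_t0: float = 10.0
    gamma_c: float = 5.0
    beta: float = 4.0
    t_sw: float = 2.0
    beta_w: float = 10.0
    a_r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_b", "alpha_m", "alpha_t"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} is an inhibition ratio; got {v!r}")
        for name in ("alpha_b0", "alpha_m0", "alpha_t0", "gamma_t0",
                     "beta", "beta_w", "t_sw"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0; got {v!r}")
        for name in ("gamma_t", "gamma_c", "a_r"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0; got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(**d)


def eruption_state(a, beta_w: float, a_r: float):
    """Map a dermal concentration to visible wheal occupancy in (0, 1).

    ``S_w(A) = 1 / (1 + exp(-beta_w (A - a_r)))`` — a sigmoid that is 0.5 at
    the visibility threshold ``a_r`` and approaches the two eruption states
    (present = 1, absent = 0) away from it. Evaluates elementwise on fields.
    """
    if not beta_w > 0:
        raise ValueError("beta_w must be > 0")
    arr = _checked(a, "A")
    out = _sigmoid(beta_w * (arr - a_r))
    return out if arr.ndim else float(out)


def hill_inhibition(h, alpha_max: float, alpha_half_sq: float):
    """Hill-type (exponent 2) inhibition ratio of histamine release.

    ``g(H) = alpha_max H^2 / (alpha_half_sq + H^2)`` — monotone
    non-decreasing in ``H``, bounded by ``alpha_max``, half-maximal at
    ``H = sqrt(alpha_half_sq)``.
    """
    if not alpha_half_sq > 0:
        raise ValueError("alpha_half_sq must be > 0")
    arr = _checked_nonneg(h, "H")
    h2 = arr * arr
    out = alpha_max * h2 / (alpha_half_sq + h2)
    return out if arr.ndim else float(out)


def tf_activation(h_b, h_m, gamma_t: float, gamma_t0: float):
    """Histamine-driven tissue-factor activation rate.

    ``f(H_B, H_M) = gamma_t (H_B + H_M) / (gamma_t0 + H_B + H_M)`` — depends
    on the two histamine pools only through their sum, so it is symmetric
    under swapping them, and saturates at ``gamma_t``.
    """
    if not gamma_t0 > 0:
        raise ValueError("gamma_t0 must be > 0")
    hb = _checked_nonneg(h_b, "H_B")
    hm = _checked_nonneg(h_m, "H_M")
    s = hb + hm
    out = gamma_t * s / (gamma_t0 + s)
    return out if np.asarray(out).ndim else float(out)


def leakage_rate(tf, gamma_c: float, beta: float, t_sw: float):
    """Sigmoidal plasma-leakage flux of coagulation factors, gated by TF.

    ``f(TF) = gamma_c / (1 + exp(-beta (TF - t_sw)))`` — a switch that turns
    leakage on once the TF concentration crosses the threshold ``t_sw``
    (default 2 ng/mL, inside the experimentally bracketed 1–3 ng/mL
    transition of endothelial gap formation).
    """
    arr = _checked(tf, "TF")
    out = gamma_c * _sigmoid(beta * (arr - t_sw))
    return out if arr.ndim else float(out)
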