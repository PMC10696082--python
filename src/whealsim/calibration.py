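"""Estimation of response-function parameters from in-vitro-style data.

Three curve families are fitted by bounded nonlinear least squares:

* Hill-2 inhibition ratio ``alpha H^2 / (alpha0 + H^2)`` — adenosine
  inhibition of histamine release from basophils / mast cells, and of
  tissue-factor expression;
* saturating activation ``gamma H / (gamma0 + H)`` — histamine-driven TF
  activation;
* a normalised sigmoid switch ``1 / (1 + exp(-beta (TF - T_sw)))`` — the
  endothelial gap-formation switch, estimated from impedance (cell-index)
  time series via the relative CI scale averaged over a fixed early window.

Each fit uses a small multi-start schedule (5 documented starting points)
so that a single bad initial guess cannot silently produce a local optimum;
non-convergent or degenerate fits are flagged in the diagnostics rather
than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_functions import hill_inhibition, tf_activation, _sigmoid

__all__ = [
    "DoseResponseDataset",
    "ImpedanceTraceSet",
    "ConversionParams",
    "FitResult",
    "fit_hill2",
    "fit_saturating1",
    "relative_ci",
    "window_mean_switch",
    "costimulus_to_histamine",
]

CI_REFERENCE_LABEL = 100.0  # reference TF concentration, ng/mL
SWITCH_WINDOW = (0.2, 0.6)  # hours; averaging window for the relative CI


@dataclass
class DoseResponseDataset:
    """Tidy (dose, response, replicate) records with stimulus metadata."""

    data: pd.DataFrame  # columns: dose, response, replicate
    stimulus: str = ""
    dose_units: str = ""

    def __post_init__(self) -> None:
        required = {"dose", "response"}
        if not required <= set(self.data.columns):
            raise ValueError("data needs 'dose' and 'response' columns")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=0)
        if (self.data["dose"] < 0).any():
            raise ValueError("doses must be >= 0")
        if not np.isfinite(self.data["response"]).all():
            raise ValueError("responses must be finite")

    @property
    def n_distinct_doses(self) -> int:
        return self.data["dose"].nunique()

    @classmethod
    def from_csv(cls, path, **meta) -> "DoseResponseDataset":
        return cls(pd.read_csv(path), **meta)


@dataclass
class ImpedanceTraceSet:
    """Cell-index traces on a shared time grid, one per TF concentration.

    ``traces`` is a DataFrame with a ``time_h`` column plus one column per
    concentration (column labels are the concentrations in ng/mL). The
    reference concentration (100 ng/mL) must be present.
    """

    traces: pd.DataFrame
    reference: float = CI_REFERENCE_LABEL

    def __post_init__(self) -> None:
        if "time_h" not in self.traces.columns:
            raise ValueError("traces need a 'time_h' column")
        self.traces = self.traces.rename(
            columns=lambda c: c if c == "time_h" else float(c))
        if self.reference not in self.concentrations:
            raise ValueError(
                f"reference concentration {self.reference} ng/mL missing")

    @property
    def time(self) -> np.ndarray:
        return self.traces["time_h"].to_numpy(float)

    @property
    def concentrations(self) -> list[float]:
        return [c for c in self.traces.columns if c != "time_h"]

    @classmethod
    def from_csv(cls, path, **kw) -> "ImpedanceTraceSet":
        return cls(pd.read_csv(path), **kw)


@dataclass
class ConversionParams:
    """Linear scale factors mapping co-stimulus doses to histamine scale.

    ``kappa_bar`` converts an LPS co-stimulus concentration to a
    histamine-equivalent concentration; ``adenosine_to_histamine`` does the
    same for adenosine. Both default to 1 (surrogates for the supplementary
    conversion, configurable).
    """

    kappa_bar: float = 1.0
    adenosine_to_histamine: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa_bar > 0 and self.adenosine_to_histamine > 0):
            raise ValueError("conversion constants must be > 0")


@dataclass
class FitResult:
    params: dict
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    def __getitem__(self, key):
        return self.params[key]


_N_STARTS = 5


def _multistart_fit(residual, starts, bounds):
    best = None
    any_ok = False
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        any_ok = any_ok or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best, any_ok


def fit_hill2(dataset: DoseResponseDataset) -> FitResult:
    """Fit the Hill-2 inhibition curve to (dose, response) records.

    Returns estimates of the maximal inhibition ratio ``alpha_max`` and the
    squared half-saturation constant ``alpha_half_sq``, with residual sum of
    squares and a convergence flag. Fitting is done on all records (not
    per-dose means), preserving the replicate error structure.
    """
    d = dataset.data
    if dataset.n_distinct_doses < 3:
        raise ValueError("need >= 3 distinct dose levels to fit")
    dose = d["dose"].to_numpy(float)
    resp = d["response"].to_numpy(float)
    if resp.min() < -0.2 or resp.max() > 1.2:
        raise ValueError("responses outside the ratio scale [-0.2, 1.2]")

    scale = np.median(dose[dose > 0]) if (dose > 0).any() else 1.0

    def residual(x):
        return hill_inhibition(dose, x[0], x[1]) - resp

    starts = [
        (0.5, scale**2),
        (0.9, scale**2),
        (max(resp.max(), 0.05), scale**2),
        (0.5, (scale / 10) ** 2),
        (0.5, (scale * 10) ** 2),
    ]
    best, ok = _multistart_fit(residual, starts,
                               bounds=([0.0, 1e-12], [1.0, np.inf]))
    alpha_max, alpha_half_sq = best.x
    degenerate = alpha_max < 1e-6 or np.ptp(resp) < 1e-12
    return FitResult(
        params={"alpha_max": float(alpha_max),
                "alpha_half_sq": float(alpha_half_sq)},
        rss=float(2 * best.cost), converged=bool(ok),
        degenerate=bool(degenerate),
        message="flat response; alpha_max unidentifiable" if degenerate else "",
    )


def fit_saturating1(dataset: DoseResponseDataset) -> FitResult:
    """Fit the exponent-1 saturating activation curve ``g H/(g0 + H)``."""
    d = dataset.data
    if dataset.n_distinct_doses < 3:
        raise ValueError("need >= 3 distinct dose levels to fit")
    dose = d["dose"].to_numpy(float)
    resp = d["response"].to_numpy(float)

    scale = np.median(dose[dose > 0]) if (dose > 0).any() else 1.0
    top = max(resp.max(), 1e-3)

    def residual(x):
        return tf_activation(dose, 0.0, x[0], x[1]) - resp

    starts = [
        (top, scale),
        (2 * top, scale),
        (top, scale / 10),
        (top, scale * 10),
        (2 * top, 2 * scale),
    ]
    best, ok = _multistart_fit(residual, starts,
                               bounds=([0.0, 1e-12], [np.inf, np.inf]))
    gamma_t, gamma_t0 = best.x
    degenerate = np.ptp(resp) < 1e-12
    return FitResult(
        params={"gamma_t": float(gamma_t), "gamma_t0": float(gamma_t0)},
        rss=float(2 * best.cost), converged=bool(ok),
        degenerate=bool(degenerate),
        message="flat response" if degenerate else "",
    )


def relative_ci(traces: ImpedanceTraceSet) -> pd.DataFrame:
    """Relative cell-index scale ``(1 - CI) / (1 - CI_ref)`` per time point.

    The reference is the 100 ng/mL trace. Time points where the reference
    gap ``1 - CI_ref`` vanishes (|1 - CI_ref| < 1e-6) are masked with NaN
    and reported in the frame's ``attrs["masked_times"]``.
    """
    ref = traces.traces[traces.reference].to_numpy(float)
    denom = 1.0 - ref
    bad = np.abs(denom) < 1e-6
    out = {"time_h": traces.time}
    for c in traces.concentrations:
        ci = traces.traces[c].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (1.0 - ci) / denom
        r[bad] = np.nan
        out[c] = r
    frame = pd.DataFrame(out)
    frame.attrs["masked_times"] = traces.time[bad].tolist()
    return frame


def _trapezoid_mean(t, y):
    if len(t) == 1:
        return float(y[0])
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def window_mean_switch(rel: pd.DataFrame,
                       window: tuple[float, float] = SWITCH_WINDOW) -> "SwitchFit":
    """Average the relative CI over the early window and fit the TF switch.

    Per concentration, the relative CI is time-averaged (trapezoidal rule)
    over the closed window (default [0.2, 0.6] h); the per-concentration
    means are then fitted with the normalised sigmoid
    ``1 / (1 + exp(-beta (TF - T_sw)))`` by bounded least squares.
    """
    t = rel["time_h"].to_numpy(float)
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("time grid does not cover the averaging window")
    concs = np.array([c for c in rel.columns if c != "time_h"], float)
    if len(concs) < 4:
        raise ValueError("need >= 4 concentrations spanning the transition")
    means = np.array([
        _trapezoid_mean(t[sel], rel[c].to_numpy(float)[sel]) for c in concs
    ])
    if np.ptp(means) < 1e-9:
        raise ValueError("window means are constant; no transition to fit")
    unbracketed = bool((means < 0.5).all() or (means > 0.5).all())

    order = np.argsort(concs)
    concs, means = concs[order], means[order]

    def residual(x):
        return _sigmoid(x[0] * (concs - x[1])) - means

    # T_sw starts bracket the observed transition; beta starts span decades.
    c_mid = concs[np.argmin(np.abs(means - 0.5))]
    starts = [(1.0, c_mid), (4.0, c_mid), (10.0, c_mid),
              (4.0, np.median(concs)), (0.5, np.median(concs))]
    best, ok = _multistart_fit(
        residual, starts,
        bounds=([1e-6, min(concs)], [np.inf, max(concs)]))
    beta, t_sw = best.x
    return SwitchFit(
        means=pd.Series(means, index=concs, name="window_mean"),
        beta=float(beta), t_sw=float(t_sw),
        rss=float(2 * best.cost), converged=bool(ok),
        unbracketed=unbracketed,
    )


@dataclass
class SwitchFit:
    means: pd.Series
    beta: float
    t_sw: float
    rss: float
    converged: bool
    unbracketed: bool


def costimulus_to_histamine(dose, params: ConversionParams,
                            kind: str = "lps"):
    """Convert a co-stimulus dose to a histamine-equivalent concentration.

    Linear rescaling: LPS doses scale by ``kappa_bar``; adenosine doses by
    the adenosine-to-histamine proportionality constant.
    """
    arr = np.asarray(dose, dtype=float)
    if np.any(arr < 0):
        raise ValueError("dose must be >= 0")
    k = params.kappa_bar if kind == "lps" else params.adenosine_to_histamine
    out = k * arr
    return out if arr.ndim else float(out)
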