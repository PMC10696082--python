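"""Extended Fourier Amplitude Sensitivity Test (eFAST), first-order indices.

Variance-based global sensitivity analysis: every parameter is driven along
a space-filling search curve

    x_i(s) = 1/2 + (1/pi) arcsin(sin(omega_i s + phi_i)),  s in [-pi, pi),

whose arcsine transform makes each marginal uniform on (0, 1). Per search
curve one parameter of interest carries the high frequency ``omega_max``
while the complementary set is assigned low, non-interfering frequencies
(<= omega_max / (2M)); the first-order index of the parameter of interest
is the spectral power at its harmonics (p * omega_max, p <= M) divided by
the total variance of the output, averaged over ``Nr`` random-phase
resamplings.

A dummy parameter that the model never reads is appended to the parameter
space; its estimated index sets the significance floor — any parameter
whose index does not exceed the dummy's is indistinguishable from
no effect, and (following the reporting rule used for the wheal-feature
analysis) a parameter is called "high" when its index is at least twice
the dummy's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpace",
    "SearchCurveDesign",
    "SensitivityResult",
    "efast_design",
    "first_order_indices",
    "min_samples",
    "kf_sensitivity_run",
]

DUMMY_NAME = "dummy"


@dataclass
class ParameterSpace:
    """Ordered parameter names with [min, max] ranges plus a dummy.

    The dummy parameter is appended automatically (unit range); it must not
    be supplied by the caller.
    """

    names: list[str]
    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if DUMMY_NAME in self.names:
            raise ValueError("the dummy parameter is appended automatically")
        for name in self.names:
            lo, hi = self.ranges[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"range of {name} must be finite with "
                                 "min < max")
        self.names = list(self.names) + [DUMMY_NAME]
        self.ranges = {**self.ranges, DUMMY_NAME: (0.0, 1.0)}

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class SearchCurveDesign:
    space: ParameterSpace
    ns: int
    m: int
    nr: int
    omega_max: int
    samples: np.ndarray    # (k_curves=k, nr, ns, k) in unit hypercube
    mapped: np.ndarray     # same, mapped to parameter ranges
    seed: int


def min_samples(m: int, omega_max: int) -> int:
    """Nyquist-driven minimal per-curve sample count ``4 M omega_max + 1``."""
    return 4 * m * omega_max + 1


def _frequencies(k: int, omega_max: int, m: int) -> np.ndarray:
    """Complementary frequencies for the k-1 non-interest parameters.

    Spread on 1..max(1, omega_max // (2M)) so that harmonics of the
    parameter of interest (p * omega_max, p <= M) stay clear of the
    complementary spectrum.
    """
    cap = max(1, omega_max // (2 * m))
    return 1 + (np.arange(k - 1) % cap)


def efast_design(space: ParameterSpace, ns: int = 65, m: int = 4,
                 nr: int = 2, seed: int = 0) -> SearchCurveDesign:
    """Build the resampled search-curve design for all parameters.

    One curve per parameter of interest (including the dummy) per phase
    resampling. ``ns`` must satisfy the Nyquist bound for the chosen
    ``omega_max = (ns - 1) // (4 m)``.
    """
    omega_max = (ns - 1) // (4 * m)
    if omega_max < 1:
        raise ValueError(
            f"ns={ns} is below the Nyquist bound; need ns >= "
            f"{min_samples(m, 1)} for M={m}")
    if ns < min_samples(m, omega_max):
        raise ValueError(
            f"ns={ns} is below the Nyquist bound {min_samples(m, omega_max)}")

    rng = np.random.default_rng(seed)
    k = space.k
    s = -np.pi + 2.0 * np.pi * np.arange(ns) / ns

    samples = np.empty((k, nr, ns, k))
    for i in range(k):
        omegas = np.empty(k)
        omegas[i] = omega_max
        comp = _frequencies(k, omega_max, m)
        omegas[[j for j in range(k) if j != i]] = comp
        for r in range(nr):
            phi = rng.uniform(0, 2 * np.pi, size=k)
            angles = np.outer(s, omegas) + phi
            samples[i, r] = 0.5 + np.arcsin(np.sin(angles)) / np.pi

    lows = np.array([space.ranges[n][0] for n in space.names])
    highs = np.array([space.ranges[n][1] for n in space.names])
    mapped = lows + samples * (highs - lows)
    return SearchCurveDesign(space=space, ns=ns, m=m, nr=nr,
                             omega_max=omega_max, samples=samples,
                             mapped=mapped, seed=seed)


@dataclass
class SensitivityResult:
    """First-order indices per output, with the dummy significance gate."""

    indices: pd.DataFrame       # rows: parameters, cols: outputs
    spread: pd.DataFrame        # resampling std of the indices
    dummy_index: pd.Series      # per output
    flags: pd.DataFrame         # high / moderate / negligible per output
    undefined: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            out: {
                p: {"index": float(self.indices.loc[p, out]),
                    "flag": str(self.flags.loc[p, out])}
                for p in self.indices.index
            }
            for out in self.indices.columns
        }


def _curve_spectrum(y: np.ndarray, omega_max: int, m: int
                    ) -> tuple[float, float]:
    """(power at the first m harmonics of omega_max, total variance)."""
    y = np.asarray(y, float)
    ns = len(y)
    coeff = np.fft.rfft(y - y.mean())
    power = (np.abs(coeff) ** 2) / ns ** 2 * 2.0
    harmonics = [p * omega_max for p in range(1, m + 1)
                 if p * omega_max < len(power)]
    return float(power[harmonics].sum()), float(power[1:].sum())


def first_order_indices(outputs: np.ndarray, design: SearchCurveDesign,
                        output_names: list[str] | None = None
                        ) -> SensitivityResult:
    """Estimate first-order indices from model outputs on the design.

    ``outputs`` has shape (k, nr, ns) for a scalar output or
    (k, nr, ns, n_out). Constant (zero-variance) outputs are flagged
    undefined rather than reported as numbers.
    """
    out = np.asarray(outputs, float)
    if out.ndim == 3:
        out = out[..., None]
    k, nr, ns, n_out = out.shape
    if (k, nr, ns) != design.samples.shape[:3]:
        raise ValueError("outputs do not match the design shape")
    names = design.space.names
    output_names = output_names or [f"y{j}" for j in range(n_out)]

    idx = np.full((k, n_out), np.nan)
    spread = np.full((k, n_out), np.nan)
    undefined = []
    for j in range(n_out):
        harm = np.full((k, nr), np.nan)
        total = np.full((k, nr), np.nan)
        for i in range(k):
            for r in range(nr):
                harm[i, r], total[i, r] = _curve_spectrum(
                    out[i, r, :, j], design.omega_max, design.m)
        # the output's total variance does not depend on which parameter
        # rides the high frequency, so pooling the per-curve totals over
        # all curves stabilises the denominator considerably
        pooled = np.nanmean(total)
        if not np.isfinite(pooled) or pooled <= 0:
            undefined.append(output_names[j])
            continue
        ratios = harm / pooled
        idx[:, j] = np.nanmean(ratios, axis=1)
        spread[:, j] = np.nanstd(ratios, axis=1)

    indices = pd.DataFrame(idx, index=names, columns=output_names)
    spread_df = pd.DataFrame(spread, index=names, columns=output_names)
    dummy = indices.loc[DUMMY_NAME]

    flags = pd.DataFrame(index=names, columns=output_names, dtype=object)
    for o in output_names:
        d = dummy[o]
        for p in names:
            v = indices.loc[p, o]
            if np.isnan(v) or np.isnan(d):
                flags.loc[p, o] = "undefined"
            elif v <= d:
                flags.loc[p, o] = "negligible"
            elif v >= 2 * d:
                flags.loc[p, o] = "high"
            else:
                flags.loc[p, o] = "moderate"
    return SensitivityResult(indices=indices, spread=spread_df,
                             dummy_index=dummy, flags=flags,
                             undefined=undefined)


KF_OUTPUTS = ["kf1_boundary", "kf2_arcs", "kf3_area", "kf4_fusion",
              "kf5_punctate"]


def _kf_outputs_for_run(series) -> np.ndarray:
    from .classifier import WhealMask, measure_features
    masks = [WhealMask(m, series.pixel_size_cm, t)
             for t, m in zip(series.times, series.masks)]
    fv = measure_features(masks)
    growth = fv.kf4_growth_rate
    if not np.isfinite(growth):
        growth = 0.0
    return np.array([
        fv.kf1_boundary_score,
        fv.kf2_arc_count,
        fv.kf3_area_score,
        float(fv.kf4_merge_events) + max(growth, 0.0),
        float(fv.kf5_punctate),
    ])


def kf_sensitivity_run(base_config, space: ParameterSpace, ns: int = 33,
                       m: int = 2, nr: int = 1, seed: int = 0,
                       max_failure_frac: float = 0.2) -> SensitivityResult:
    """eFAST of the five wheal key features against kinetic parameters.

    For each design point the named kinetic/response parameters of
    ``base_config`` are replaced by the sampled values, a reduced-scale
    simulation is run, and the five feature scores (annularity, arc count,
    area score, fusion, punctate) are measured on the resulting mask
    series. Failed or degenerate runs are imputed with the per-curve median
    (keeping the Fourier grid intact) up to ``max_failure_frac``.
    """
    import copy

    from .simulator import SimConfig, run

    design = efast_design(space, ns=ns, m=m, nr=nr, seed=seed)
    k, nr_, ns_ = design.samples.shape[:3]
    outputs = np.full((k, nr_, ns_, len(KF_OUTPUTS)), np.nan)
    n_failed = 0
    total = k * nr_ * ns_
    for i in range(k):
        for r in range(nr_):
            for t in range(ns_):
                cfg = copy.deepcopy(base_config)
                for j, name in enumerate(design.space.names):
                    if name == DUMMY_NAME:
                        continue
                    val = float(design.mapped[i, r, t, j])
                    if hasattr(cfg.kinetics, name):
                        setattr(cfg.kinetics, name, val)
                    elif hasattr(cfg.kinetics.response, name):
                        setattr(cfg.kinetics.response, name, val)
                    else:
                        raise KeyError(f"unknown model parameter {name!r}")
                try:
                    series = run(cfg, seed=cfg.seed)
                    outputs[i, r, t] = _kf_outputs_for_run(series)
                except Exception:
                    n_failed += 1
                    if n_failed > max_failure_frac * total:
                        raise RuntimeError(
                            f"{n_failed}/{total} simulations failed; "
                            "aborting the sensitivity run")
            # impute failures with the per-curve median
            for j in range(len(KF_OUTPUTS)):
                col = outputs[i, r, :, j]
                bad = np.isnan(col)
                if bad.any() and not bad.all():
                    col[bad] = np.nanmedian(col)
    return first_order_indices(outputs, design, output_names=KF_OUTPUTS)
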