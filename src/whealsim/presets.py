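"""Calibrated simulation presets for the five eruption-pattern regimes.

The kinetic values here are calibration surrogates located by a coarse
regime search over the mast-cell network axes (release rate ``gamma_m``,
histamine decay ``mu_m``, maximal release inhibition ``alpha_m``) on a
zoomed 12.8 cm dermal patch at 64 x 64 resolution; they are not a unique
fit to any dataset. The shared base configuration keeps every other
parameter fixed so that moving only along those three axes reproduces the
whole pattern repertoire:

* strong release with slow decay drives an excitation front whose wake is
  depleted of mast-cell histamine — an expanding ring (annular), which
  breaks into arcs where patches of the dermis carry no mast cells
  (broken-annular);
* moderate release sustains the wheal interior — filled wheals that grow
  and fuse (geographic) or stay isolated (circular);
* weak release (or fast decay, or saturating inhibition) cannot recruit
  the mast-cell sheet at all — only small static spots above the basophil
  adhesion sites remain (dot).

The domain is a viewport onto the dermis: 12.8 cm at h = 0.2 cm/px keeps
the clinical 1 cm dot rule at 5 px while a 35 cm sheet at the same spacing
would need N = 175.
"""

from __future__ import annotations

import copy

from .model_functions import ResponseParams
from .simulator import DermisGrid, KineticParameters, SimConfig

__all__ = [
    "base_config",
    "pattern_preset",
    "sweep_axes",
    "pattern_repertoire_sweep",
    "PATTERN_PRESETS",
    "SWEEP_AXES",
]

# per-regime overrides of the shared base configuration; the first three
# keys are the mast-cell network axes, the rest are run-design choices
# (circular wheals emerge from sparse, larger stimulation foci with slow
# spread; a fully occupied mast sheet keeps annular fronts closed while
# depleted patches break them into arcs)
PATTERN_PRESETS: dict[str, dict[str, float]] = {
    "annular": {"gamma_m": 3.0, "mu_m": 0.25, "alpha_m": 0.95,
                "mast_occupancy": 1.0},
    "broken-annular": {"gamma_m": 4.5, "mu_m": 0.25, "alpha_m": 0.6,
                       "mast_occupancy": 0.85},
    "geographic": {"gamma_m": 3.0, "mu_m": 0.35, "alpha_m": 0.3},
    "circular": {"gamma_m": 1.0, "mu_m": 0.5, "alpha_m": 0.6,
                 "site_radius_px": 3, "site_min_sep_frac": 0.3},
    "dot": {"gamma_m": 0.8, "mu_m": 0.7, "alpha_m": 0.95},
}

# calibrated sweep ranges of the three mast-cell network axes
SWEEP_AXES: dict[str, tuple[float, ...]] = {
    "gamma_m": (0.8, 3.0, 4.5),
    "mu_m": (0.25, 0.35, 0.7),
    "alpha_m": (0.3, 0.6, 0.95),
}


def base_config(seed: int = 0) -> SimConfig:
    """Shared base configuration of the pattern-regime study."""
    response = ResponseParams(
        gamma_t=5.0, gamma_t0=8.0,
        alpha_b=0.9, alpha_b0=25.0,
        alpha_m=0.6, alpha_m0=25.0,
        alpha_t=0.8, alpha_t0=100.0,
        gamma_c=24.0, beta=6.0, t_sw=2.0,
        beta_w=10.0, a_r=4.0,
    )
    kinetics = KineticParameters(
        delta_b=0.01, delta_t=0.05, delta_m=0.01,
        mu_b=1.0, mu_t=0.6, mu_m=0.35, mu_c=2.0,
        gamma_b=4.0, gamma_m=3.0,
        d_c=0.3, d_m=0.04,
        response=response,
    )
    return SimConfig(
        grid=DermisGrid(length_cm=12.8, n=64),
        kinetics=kinetics,
        n_sites=2, site_radius_px=2, site_margin_frac=0.25,
        site_min_sep_frac=0.2,
        basophil_capacity=400.0,
        mast_capacity=10.0,
        mast_heterogeneity=0.15,
        mast_heterogeneity_scale_px=3.0,
        mast_occupancy=0.9,
        hb_stimulus=10.0, hm_noise=0.01,
        t_end=42.0, snapshot_interval=4.0,
        seed=seed,
    )


def pattern_preset(pattern: str, seed: int = 0) -> SimConfig:
    """Base configuration moved to the named regime's (gamma_m, mu_m, alpha_m)."""
    if pattern not in PATTERN_PRESETS:
        raise ValueError(f"unknown pattern preset {pattern!r}; "
                         f"choose from {sorted(PATTERN_PRESETS)}")
    cfg = base_config(seed=seed)
    for key, value in PATTERN_PRESETS[pattern].items():
        if hasattr(cfg.kinetics, key):
            setattr(cfg.kinetics, key, value)
        elif hasattr(cfg.kinetics.response, key):
            setattr(cfg.kinetics.response, key, value)
        else:
            setattr(cfg, key, value)
    return cfg


def sweep_axes() -> dict[str, tuple[float, ...]]:
    """Copy of the calibrated (gamma_m, mu_m, alpha_m) sweep ranges."""
    return copy.deepcopy(SWEEP_AXES)


def pattern_repertoire_sweep(seed: int = 0, seeds_per_cell: int = 3,
                             axes: dict | None = None):
    """Sweep the three mast-cell axes and classify every run.

    Every (gamma_m, mu_m, alpha_m) cell of the axis grid is simulated with
    ``seeds_per_cell`` independent replicates (sub-seeds expanded from the
    global seed by a fixed counter scheme, so each run sees its own site
    placement and mast-density realization). Returns a list of records
    ``{gamma_m, mu_m, alpha_m, seed, label}``; runs without any eruption
    are labelled "none".
    """
    from .classifier import WhealMask, classify_series
    from .simulator import run

    axes = axes or SWEEP_AXES
    records = []
    idx = 0
    for gm in axes["gamma_m"]:
        for mm in axes["mu_m"]:
            for am in axes["alpha_m"]:
                for _ in range(seeds_per_cell):
                    idx += 1
                    sub = (seed * 100003 + idx * 7919) % (2 ** 31)
                    cfg = base_config(seed=sub)
                    cfg.kinetics.gamma_m = gm
                    cfg.kinetics.mu_m = mm
                    cfg.kinetics.response.alpha_m = am
                    series = run(cfg)
                    masks = [WhealMask(m, series.pixel_size_cm, t)
                             for t, m in zip(series.times, series.masks)]
                    try:
                        label = classify_series(masks).type_
                    except ValueError:
                        label = "none"
                    records.append({"gamma_m": gm, "mu_m": mm,
                                    "alpha_m": am, "seed": sub,
                                    "label": label})
    return records
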