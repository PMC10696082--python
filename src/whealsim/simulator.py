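"""Reaction–diffusion simulator of wheal formation on a 2D dermis sheet.

The dermis is modelled as a thin square sheet (default 35 cm x 35 cm) with
the intravascular space distributed homogeneously across it. Four variables
are evolved:

* ``[H_B]`` — histamine released from basophils, an ODE on the basophil
  adhesion sites (small random disks of the endothelium);
* ``[TF]`` — tissue-factor expression, an ODE at every pixel, activated by
  the local histamine pool (basophil contribution only inside sites);
* ``[C]`` — coagulation factors leaked from blood vessels, diffusing, with
  a sigmoidal TF-gated leakage source;
* ``[H_M]`` — histamine released from dermal mast cells, diffusing, with a
  coagulation-factor-driven release source.

Basophils and mast cells hold finite histamine reservoirs: release
decrements the reservoir and stops once it is exhausted (a Heaviside
indicator that switches 1 -> 0 exactly once per site/pixel). Time stepping
is an explicit operator-split Euler scheme — pointwise reactions, then
5-point Laplacian diffusion with zero-flux boundaries — with the time step
held below the diffusion stability bound ``h^2 / (4 max(D))``.

The visible output of a run is a series of eruption-state snapshots
``S_w([C])``: the wheal is plotted from the coagulation-factor field (the
mast-cell histamine field patterns identically).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model_functions import (
    ResponseParams, eruption_state, hill_inhibition, leakage_rate,
    tf_activation,
)

__all__ = [
    "DermisGrid",
    "CellOccupancy",
    "KineticParameters",
    "SimulationState",
    "SnapshotSeries",
    "SimConfig",
    "build_domain",
    "step",
    "run",
    "mass_ledger",
    "stability_dt",
]

SAFETY_FACTOR = 0.9


@dataclass
class DermisGrid:
    """Square dermal domain with an N x N pixel-centred grid.

    Physical coordinates of pixel (i, j) are ((i + 0.5) h, (j + 0.5) h),
    row-major, 0-based; ``h = length_cm / n``.
    """

    length_cm: float = 35.0
    n: int = 256
    boundary: str = "neumann"

    def __post_init__(self) -> None:
        if self.n < 16:
            raise ValueError("grid resolution n must be >= 16")
        if self.length_cm <= 0:
            raise ValueError("domain length must be > 0")
        if self.boundary != "neumann":
            raise ValueError("only zero-flux (neumann) boundaries supported")

    @property
    def h(self) -> float:
        return self.length_cm / self.n


@dataclass
class CellOccupancy:
    """Basophil adhesion sites and per-cell histamine reservoirs.

    ``site_map`` labels each pixel with its basophil-site index (-1 where
    none); ``basophil_reservoir`` holds the remaining histamine content per
    site and ``mast_reservoir`` per pixel. The Heaviside release indicators
    are always derived as ``reservoir > 0``, never stored.
    """

    site_map: np.ndarray            # int, n x n, -1 = no site
    site_pixels: list[np.ndarray]   # flat pixel indices per site
    basophil_reservoir: np.ndarray  # per site
    mast_reservoir: np.ndarray      # per pixel, n x n
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.site_pixels)

    @property
    def chi_b(self) -> np.ndarray:
        return self.basophil_reservoir > 0

    @property
    def chi_m(self) -> np.ndarray:
        return self.mast_reservoir > 0


@dataclass
class KineticParameters:
    """Rate constants of the four-variable network.

    ``delta_*`` are basal production rates, ``mu_*`` basal decay rates,
    ``gamma_b`` / ``gamma_m`` histamine release rates of basophils and mast
    cells, and ``d_c`` / ``d_m`` the diffusion coefficients (cm^2 per model
    time unit) of coagulation factors and mast-cell histamine. The embedded
    :class:`ResponseParams` carries the calibrated response-function shapes.
    """

    delta_b: float = 0.01
    delta_t: float = 0.05
    delta_m: float = 0.01
    mu_b: float = 1.0
    mu_t: float = 1.0
    mu_m: float = 0.4
    mu_c: float = 0.6
    gamma_b: float = 2.0
    gamma_m: float = 3.0
    d_c: float = 0.3
    d_m: float = 0.1
    response: ResponseParams = field(default_factory=ResponseParams)

    def __post_init__(self) -> None:
        for name in ("delta_b", "delta_t", "delta_m", "mu_b", "mu_t",
                     "mu_m", "mu_c", "gamma_b", "gamma_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.d_c > 0 and self.d_m > 0):
            raise ValueError("diffusion coefficients must be > 0")
        if isinstance(self.response, dict):
            self.response = ResponseParams(**self.response)


@dataclass
class SimulationState:
    grid: DermisGrid
    occupancy: CellOccupancy
    h_b: np.ndarray   # per basophil site
    tf: np.ndarray    # n x n
    c: np.ndarray     # n x n
    h_m: np.ndarray   # n x n
    t: float = 0.0
    # discrete mass-balance accumulators for [C] (area-weighted integrals)
    cum_leak: float = 0.0
    cum_decay: float = 0.0
    released_b: float = 0.0
    released_m: float = 0.0

    def copy(self) -> "SimulationState":
        return SimulationState(
            grid=self.grid,
            occupancy=CellOccupancy(
                site_map=self.occupancy.site_map,
                site_pixels=self.occupancy.site_pixels,
                basophil_reservoir=self.occupancy.basophil_reservoir.copy(),
                mast_reservoir=self.occupancy.mast_reservoir.copy(),
                seed=self.occupancy.seed,
            ),
            h_b=self.h_b.copy(), tf=self.tf.copy(),
            c=self.c.copy(), h_m=self.h_m.copy(), t=self.t,
            cum_leak=self.cum_leak, cum_decay=self.cum_decay,
            released_b=self.released_b, released_m=self.released_m,
        )


@dataclass
class SnapshotSeries:
    """Time-stamped eruption-state fields / binary wheal masks of one run."""

    times: list[float]
    fields: list[np.ndarray]        # S_w([C]) per snapshot
    masks: list[np.ndarray]         # bool per snapshot
    pixel_size_cm: float
    config: dict
    ledger: list[dict]              # per-snapshot mass-balance records
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("snapshot times must be strictly increasing")


@dataclass
class SimConfig:
    """Full configuration of one simulation run."""

    grid: DermisGrid = field(default_factory=lambda: DermisGrid(n=64))
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    n_sites: int = 12
    site_radius_px: int = 2
    site_margin_frac: float = 0.0  # keep sites this fraction away from walls
    site_min_sep_frac: float = 0.0  # minimal centre separation (fraction of L)
    basophil_capacity: float = 50.0
    mast_capacity: float = 30.0
    mast_heterogeneity: float = 0.0   # relative spread of mast capacity
    mast_heterogeneity_scale_px: float = 3.0  # correlation length of spread
    mast_occupancy: float = 1.0       # fraction of pixels holding mast cells
    hb_stimulus: float = 10.0          # initial basophil histamine at sites
    hm_noise: float = 0.01             # multiplicative uniform noise on H_M
    t_end: float = 60.0
    dt: float | None = None            # None -> stability-bound default
    dt_max: float = 0.05
    snapshot_interval: float = 5.0
    binarize_theta: float = 0.5
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(d)
        grid = DermisGrid(**d.pop("grid", {}))
        kin = d.pop("kinetics", {})
        resp = kin.pop("response", {})
        kinetics = KineticParameters(response=ResponseParams(**resp), **kin)
        known = set(cls.__dataclass_fields__) - {"grid", "kinetics"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(grid=grid, kinetics=kinetics, **d)

    def to_dict(self) -> dict:
        kin = {k: getattr(self.kinetics, k)
               for k in KineticParameters.__dataclass_fields__
               if k != "response"}
        kin["response"] = self.kinetics.response.to_dict()
        out = {"grid": {"length_cm": self.grid.length_cm, "n": self.grid.n,
                        "boundary": self.grid.boundary},
               "kinetics": kin}
        for k in self.__dataclass_fields__:
            if k not in ("grid", "kinetics"):
                out[k] = getattr(self, k)
        return out


def stability_dt(grid: DermisGrid, kp: KineticParameters) -> float:
    """Maximal admissible explicit-diffusion step ``h^2 / (4 max(D))``."""
    return grid.h ** 2 / (4.0 * max(kp.d_c, kp.d_m))


def build_domain(config: SimConfig, seed: int | None = None
                 ) -> tuple[DermisGrid, CellOccupancy, SimulationState]:
    """Place basophil sites and assemble the basal initial state.

    Sites are non-overlapping random disks (count and radius from config).
    Initial fields sit at the basal production/decay balance
    (``H* = delta/mu``; ``C* = f_leak(TF*)/mu_c``) with a seeded
    multiplicative perturbation on ``[H_M]`` and the configured basophil
    stimulus applied at the sites.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    grid, kp = config.grid, config.kinetics
    n = grid.n

    site_map = np.full((n, n), -1, dtype=np.int32)
    site_pixels: list[np.ndarray] = []
    r = config.site_radius_px
    ii, jj = np.mgrid[0:n, 0:n]
    max_tries = 200 * max(config.n_sites, 1)
    tries = 0
    # centres are drawn in unit (physical) coordinates so a site layout is
    # reproducible across grid refinements of the same seed
    lo = config.site_margin_frac + r / n
    hi = 1.0 - config.site_margin_frac - r / n
    if hi <= lo:
        raise ValueError("site margin leaves no room for site placement")
    min_sep = max((2 * r + 1) / n, config.site_min_sep_frac)
    centers: list[np.ndarray] = []
    while len(site_pixels) < config.n_sites:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {config.n_sites} non-overlapping sites of "
                f"radius {r} px on a {n}x{n} grid")
        tries += 1
        cand = rng.uniform(lo, hi, size=2)
        if any(np.hypot(*(cand - c)) < min_sep for c in centers):
            continue
        ci, cj = cand * n
        disk = (ii + 0.5 - ci) ** 2 + (jj + 0.5 - cj) ** 2 <= r ** 2
        if not disk.any():
            continue
        site_map[disk] = len(site_pixels)
        site_pixels.append(np.flatnonzero(disk.ravel()))
        centers.append(cand)

    mast_cap = np.full((n, n), config.mast_capacity, dtype=float)
    scale = config.mast_heterogeneity_scale_px
    if config.mast_heterogeneity > 0:
        # spatially correlated mast-cell density: unit-variance smoothed
        # noise, clipped so depleted patches have zero (not negative) content
        noise = rng.standard_normal((n, n))
        if scale > 0:
            noise = ndimage.gaussian_filter(noise, scale, mode="wrap")
            noise /= noise.std() or 1.0
        mast_cap *= np.clip(1.0 + config.mast_heterogeneity * noise, 0.0, None)
    if not 0.0 < config.mast_occupancy <= 1.0:
        raise ValueError("mast_occupancy must lie in (0, 1]")
    if config.mast_occupancy < 1.0:
        # correlated binary occupancy: patches without mast cells never
        # release histamine, so excitation fronts cannot pass through them
        occ_noise = rng.standard_normal((n, n))
        if scale > 0:
            occ_noise = ndimage.gaussian_filter(occ_noise, scale, mode="wrap")
        thresh = np.quantile(occ_noise, 1.0 - config.mast_occupancy)
        mast_cap *= occ_noise >= thresh
    occ = CellOccupancy(
        site_map=site_map,
        site_pixels=site_pixels,
        basophil_reservoir=np.full(len(site_pixels),
                                   float(config.basophil_capacity)),
        mast_reservoir=mast_cap,
        seed=seed,
    )

    rp = kp.response
    hb0 = (kp.delta_b / kp.mu_b if kp.mu_b > 0 else 0.0) + config.hb_stimulus
    tf0 = kp.delta_t / kp.mu_t if kp.mu_t > 0 else 0.0
    c0 = (leakage_rate(tf0, rp.gamma_c, rp.beta, rp.t_sw) / kp.mu_c
          if kp.mu_c > 0 else 0.0)
    hm0 = kp.delta_m / kp.mu_m if kp.mu_m > 0 else 0.0

    h_m = np.full((n, n), hm0)
    if config.hm_noise > 0:
        h_m *= 1.0 + config.hm_noise * rng.uniform(-1, 1, (n, n))

    state = SimulationState(
        grid=grid, occupancy=occ,
        h_b=np.full(len(site_pixels), hb0),
        tf=np.full((n, n), tf0),
        c=np.full((n, n), c0),
        h_m=h_m,
    )
    return grid, occ, state


def _laplacian(a: np.ndarray, h: float) -> np.ndarray:
    # 5-point stencil; 'nearest' edge replication realises zero-flux walls
    # and keeps the discrete integral exactly conserved.
    return ndimage.laplace(a, mode="nearest") / (h * h)


def step(state: SimulationState, kp: KineticParameters, dt: float
         ) -> SimulationState:
    """Advance one operator-split Euler step (reactions, then diffusion).

    Raises if ``dt`` violates the diffusion stability bound or if any field
    would turn negative (a scheme-bug guard, not an expected event).
    """
    bound = stability_dt(state.grid, kp)
    if dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} violates the diffusion stability bound; "
            f"maximal admissible dt is {bound:.6g}")

    s = state.copy()
    occ = s.occupancy
    rp = kp.response
    h = s.grid.h
    area = h * h

    chi_b = occ.chi_b
    chi_m = occ.chi_m

    # --- pointwise reactions (all terms evaluated at the current state) ---
    if occ.n_sites:
        tf_site = np.array([state.tf.ravel()[px].mean()
                            for px in occ.site_pixels])
        rel_b = (kp.gamma_b * tf_site * chi_b
                 * (1.0 - hill_inhibition(state.h_b, rp.alpha_b, rp.alpha_b0)))
        s.h_b = state.h_b + dt * (kp.delta_b + rel_b - kp.mu_b * state.h_b)
        occ.basophil_reservoir = np.maximum(
            occ.basophil_reservoir - rel_b * dt, 0.0)
        s.released_b += float(np.sum(rel_b) * dt)
    else:
        rel_b = np.zeros(0)

    hb_grid = np.zeros_like(state.tf)
    for k, px in enumerate(occ.site_pixels):
        hb_grid.ravel()[px] = state.h_b[k]

    act = tf_activation(hb_grid, state.h_m, rp.gamma_t, rp.gamma_t0)
    inh_t = hill_inhibition(hb_grid + state.h_m, rp.alpha_t, rp.alpha_t0)
    s.tf = state.tf + dt * (kp.delta_t + act * (1.0 - inh_t)
                            - kp.mu_t * state.tf)

    leak = leakage_rate(state.tf, rp.gamma_c, rp.beta, rp.t_sw)
    s.c = state.c + dt * (leak - kp.mu_c * state.c)
    s.cum_leak += float(leak.sum() * area * dt)
    s.cum_decay += float(kp.mu_c * state.c.sum() * area * dt)

    rel_m = (kp.gamma_m * state.c * chi_m
             * (1.0 - hill_inhibition(state.h_m, rp.alpha_m, rp.alpha_m0)))
    s.h_m = state.h_m + dt * (kp.delta_m + rel_m - kp.mu_m * state.h_m)
    occ.mast_reservoir = np.maximum(occ.mast_reservoir - rel_m * dt, 0.0)
    s.released_m += float(rel_m.sum() * area * dt)

    # --- diffusion (conservative; zero-flux boundaries) ---
    s.c += dt * kp.d_c * _laplacian(s.c, h)
    s.h_m += dt * kp.d_m * _laplacian(s.h_m, h)

    for name, f in (("H_B", s.h_b), ("TF", s.tf), ("C", s.c), ("H_M", s.h_m)):
        if f.size and (not np.all(np.isfinite(f)) or f.min() < 0):
            raise RuntimeError(
                f"field {name} left [0, inf) at t={state.t + dt:.4g}; "
                "reduce dt (reaction stiffness exceeds the explicit scheme)")

    s.t = state.t + dt
    return s


def run(config: SimConfig, seed: int | None = None) -> SnapshotSeries:
    """Integrate to ``t_end``, recording eruption-state snapshots.

    The time step defaults to the diffusion stability bound times a 0.9
    safety factor, additionally capped by ``dt_max`` for reaction accuracy.
    The run log records the step used, total released histamine and the
    mast-reservoir exhaustion history.
    """
    grid, occ, state = build_domain(config, seed=seed)
    kp = config.kinetics
    rp = kp.response

    bound = stability_dt(grid, kp)
    dt = config.dt if config.dt is not None else min(
        SAFETY_FACTOR * bound, config.dt_max)
    if dt > bound:
        raise ValueError(
            f"configured dt={dt} exceeds the stability bound {bound:.6g}")

    n_steps = int(round(config.t_end / dt))
    snap_every = max(1, int(round(config.snapshot_interval / dt)))

    times, fields, masks, ledger = [], [], [], []
    exhaustion = []

    def record(st: SimulationState):
        sw = eruption_state(st.c, rp.beta_w, rp.a_r)
        times.append(st.t)
        fields.append(sw)
        masks.append(sw >= config.binarize_theta)
        area = grid.h ** 2
        ledger.append({
            "t": st.t,
            "total_c": float(st.c.sum() * area),
            "cum_leak": st.cum_leak,
            "cum_decay": st.cum_decay,
        })
        exhaustion.append({
            "t": st.t,
            "mast_exhausted_frac": float(np.mean(~st.occupancy.chi_m)),
            "basophil_exhausted_frac": float(np.mean(~st.occupancy.chi_b))
            if st.occupancy.n_sites else 0.0,
        })

    record(state)
    for k in range(n_steps):
        state = step(state, kp, dt)
        if (k + 1) % snap_every == 0 or k == n_steps - 1:
            if state.t > times[-1]:
                record(state)

    return SnapshotSeries(
        times=times, fields=fields, masks=masks,
        pixel_size_cm=grid.h,
        config=config.to_dict(),
        ledger=ledger,
        log={
            "dt": dt,
            "stability_bound": bound,
            "n_steps": n_steps,
            "released_histamine_basophils": state.released_b,
            "released_histamine_mast": state.released_m,
            "exhaustion": exhaustion,
        },
    )


def mass_ledger(series: SnapshotSeries, tol: float = 1e-8) -> dict:
    """Check the discrete mass balance of [C] across the recorded run.

    With zero-flux boundaries the scheme satisfies, step by step,
    ``∫C(t) = ∫C(0) + ∫∫ f_leak - mu_c ∫∫ C`` exactly; this report returns
    the maximal residual of that identity over the snapshots.
    """
    rows = series.ledger
    base = rows[0]
    residuals = [
        r["total_c"] - (base["total_c"]
                        + (r["cum_leak"] - base["cum_leak"])
                        - (r["cum_decay"] - base["cum_decay"]))
        for r in rows
    ]
    scale = max(abs(r["total_c"]) for r in rows) or 1.0
    max_resid = max(abs(x) for x in residuals)
    return {
        "max_residual": max_resid,
        "max_relative_residual": max_resid / scale,
        "passed": bool(max_resid / scale <= tol),
        "residuals": residuals,
    }
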