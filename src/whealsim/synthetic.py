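"""Seeded generators for every input class the pipeline consumes.

Nothing here requires a download: dose–response tables, impedance-like
cell-index traces, inter-rater vote matrices with controlled concordance
and ground-truth wheal-mask series (rings, broken rings, merging disks,
sparse disks, static dots) are all produced programmatically with an
explicit seed, and the generating truth is embedded in the returned
object's metadata so round-trip (generate-and-refit) tests can assert
recovery.

Noise is additive Gaussian on the ratio scales, truncated to the valid
range, emulating the mean ± SD structure of replicated in vitro readouts.
The default fixture pixel size is 0.1 cm/px, so the 1 cm punctate rule
corresponds to 10 px.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import DoseResponseDataset, ImpedanceTraceSet
from .classifier import WhealMask
from .model_functions import hill_inhibition, tf_activation, _sigmoid
from .vote_stats import EGE_TYPES, NON_QUALIFYING, VoteMatrix

__all__ = [
    "gen_dose_response",
    "gen_impedance_traces",
    "gen_vote_matrix",
    "gen_mask_fixtures",
    "FIXTURE_PIXEL_SIZE_CM",
]

FIXTURE_PIXEL_SIZE_CM = 0.1


def gen_dose_response(truth: dict, noise_sd: float = 0.0, n_doses: int = 8,
                      n_reps: int = 3, seed: int = 0,
                      kind: str = "hill2",
                      dose_range: tuple[float, float] = (0.1, 100.0),
                      ) -> DoseResponseDataset:
    """Dose–response records from the Hill-2 or saturating-1 curve + noise.

    ``truth`` holds ``(alpha_max, alpha_half_sq)`` for ``kind="hill2"`` or
    ``(gamma_t, gamma_t0)`` for ``kind="saturating1"``. Doses are
    log-spaced; responses are truncated to the ratio scale [-0.2, 1.2]
    only for the inhibition-ratio family.
    """
    rng = np.random.default_rng(seed)
    doses = np.geomspace(dose_range[0], dose_range[1], n_doses)
    if kind == "hill2":
        clean = hill_inhibition(doses, truth["alpha_max"],
                                truth["alpha_half_sq"])
    elif kind == "saturating1":
        clean = tf_activation(doses, 0.0, truth["gamma_t"], truth["gamma_t0"])
    else:
        raise ValueError(f"unknown curve kind {kind!r}")

    rows = []
    for rep in range(n_reps):
        resp = clean + (rng.normal(0.0, noise_sd, n_doses)
                        if noise_sd > 0 else 0.0)
        if kind == "hill2":
            resp = np.clip(resp, -0.2, 1.2)
        rows.append(pd.DataFrame({
            "dose": doses, "response": resp, "replicate": rep}))
    ds = DoseResponseDataset(pd.concat(rows, ignore_index=True),
                             stimulus=f"synthetic-{kind}")
    ds.data.attrs["truth"] = dict(truth)
    ds.data.attrs["seed"] = seed
    return ds


def gen_impedance_traces(t_sw: float = 2.0, beta: float = 4.0,
                         time_h: np.ndarray | None = None,
                         concentrations: tuple[float, ...] = (
                             0.1, 0.5, 1.0, 2.0, 3.0, 10.0, 100.0),
                         noise_sd: float = 0.0, seed: int = 0,
                         ) -> ImpedanceTraceSet:
    """Cell-index traces whose window-averaged relative scale is sigmoidal.

    The reference trace (100 ng/mL) drops from CI = 1 toward a plateau; each
    other concentration's gap ``1 - CI`` is the reference gap scaled by the
    target switch value ``sigmoid(beta (conc - t_sw))``, so the constructed
    relative CI reproduces the switch curve exactly in the noiseless case.
    """
    rng = np.random.default_rng(seed)
    if time_h is None:
        time_h = np.arange(0.0, 1.01, 0.05)
    time_h = np.asarray(time_h, float)
    if 100.0 not in concentrations:
        raise ValueError("reference concentration 100 ng/mL must be present")

    ref_gap = 0.6 * (1.0 - np.exp(-5.0 * time_h))  # reference 1 - CI
    data = {"time_h": time_h}
    for c in concentrations:
        target = 1.0 if c == 100.0 else float(_sigmoid(beta * (c - t_sw)))
        gap = target * ref_gap
        if noise_sd > 0 and c != 100.0:
            gap = gap + rng.normal(0.0, noise_sd * ref_gap.max(), len(time_h))
        data[c] = 1.0 - gap
    ts = ImpedanceTraceSet(pd.DataFrame(data))
    ts.traces.attrs["truth"] = {"t_sw": t_sw, "beta": beta}
    return ts


def gen_vote_matrix(n_samples: int = 105, n_raters: int = 6,
                    n_unanimous: int = 92, seed: int = 0,
                    discordant_style: str = "split") -> VoteMatrix:
    """Vote matrix with an exact unanimity structure.

    ``n_unanimous`` samples receive all-identical qualifying-type votes
    (types cycled deterministically); the rest are discordant: either an
    even "split" across distinct labels (modal count 2 at 6 raters) or
    "non_qualifying" (all raters vote uniform/NA).
    """
    if n_unanimous > n_samples:
        raise ValueError("n_unanimous cannot exceed n_samples")
    if n_raters < 1:
        raise ValueError("need >= 1 rater")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        if i < n_unanimous:
            t = EGE_TYPES[i % len(EGE_TYPES)]
            rows.append([t] * n_raters)
        elif discordant_style == "non_qualifying":
            rows.append([NON_QUALIFYING[j % 2] for j in range(n_raters)])
        else:
            # pair-split votes over mixed labels: modal qualifying count
            # stays below the rater count, so SB < 1
            labels = list(EGE_TYPES[:3]) + list(NON_QUALIFYING)
            picks = rng.choice(len(labels), size=3, replace=False)
            votes = [labels[p] for p in picks for _ in (0, 1)]
            rows.append((votes * ((n_raters // len(votes)) + 1))[:n_raters])
    order = rng.permutation(n_samples)
    df = pd.DataFrame([rows[i] for i in order],
                      index=[f"s{i:03d}" for i in range(n_samples)],
                      columns=[f"rater_{j + 1}" for j in range(n_raters)])
    return VoteMatrix(df)


def _disk(n: int, ci: float, cj: float, r: float) -> np.ndarray:
    ii, jj = np.mgrid[0:n, 0:n]
    return (ii - ci) ** 2 + (jj - cj) ** 2 <= r ** 2


def _ring(n, ci, cj, r_out, r_in) -> np.ndarray:
    return _disk(n, ci, cj, r_out) & ~_disk(n, ci, cj, r_in)


def _remove_sectors(mask, ci, cj, n_gaps, gap_deg, start) -> np.ndarray:
    n = mask.shape[0]
    ii, jj = np.mgrid[0:n, 0:n]
    ang = np.degrees(np.arctan2(ii - ci, jj - cj)) % 360.0
    out = mask.copy()
    for k in range(n_gaps):
        a0 = (start + k * 360.0 / n_gaps) % 360.0
        span = (ang - a0) % 360.0
        out &= ~(span < gap_deg)
    return out


def gen_mask_fixtures(pattern: str, n_frames: int = 5, seed: int = 0,
                      grid_n: int = 128,
                      pixel_size_cm: float = FIXTURE_PIXEL_SIZE_CM,
                      ) -> tuple[list[WhealMask], str]:
    """Ground-truth mask series for one of the five EGe patterns.

    Geometry is randomized (centres, radii, gap phases) under the seed while
    honouring each type's defining constraints: rings grow keeping a closed
    (annular) or sector-broken (broken-annular) boundary; geographic disks
    grow until they merge; circular disks are sparse, >= 1 cm and slow;
    dots stay < 1 cm and static. Returns the series and its true label.
    """
    if pattern not in EGE_TYPES:
        raise ValueError(f"pattern must be one of {EGE_TYPES}")
    rng = np.random.default_rng(seed)
    n = grid_n
    frames: list[np.ndarray] = []
    px_per_cm = 1.0 / pixel_size_cm

    if pattern in ("annular", "broken-annular"):
        ci, cj = rng.uniform(0.4 * n, 0.6 * n, size=2)
        thick = rng.uniform(6, 10)
        r0 = rng.uniform(10, 14)
        growth = rng.uniform(3, 5)
        n_gaps = rng.integers(2, 5)
        gap_deg = rng.uniform(8, 14)
        phase = rng.uniform(0, 360)
        for k in range(n_frames):
            r_out = r0 + growth * k
            ring = _ring(n, ci, cj, r_out, r_out - thick)
            if pattern == "broken-annular":
                ring = _remove_sectors(ring, ci, cj, n_gaps, gap_deg, phase)
            frames.append(ring)

    elif pattern == "geographic":
        # chain placement: consecutive disks start separated by a small gap
        # that the growth closes mid-series, guaranteeing merge events
        k_disks = int(rng.integers(3, 6))
        radii = rng.uniform(6, 9, size=k_disks)
        growth = rng.uniform(2.5, 4.0)
        centers = [rng.uniform(0.45 * n, 0.55 * n, size=2)]
        for i in range(1, k_disks):
            for _ in range(200):
                theta = rng.uniform(0, 2 * np.pi)
                d = radii[i - 1] + radii[i] + rng.uniform(3, 6)
                cand = centers[i - 1] + d * np.array([np.cos(theta),
                                                      np.sin(theta)])
                if np.all((cand > 0.12 * n) & (cand < 0.88 * n)) and all(
                        np.hypot(*(cand - c)) > radii[i] + radii[j] + 2
                        for j, c in enumerate(centers)):
                    centers.append(cand)
                    break
            else:
                raise RuntimeError("could not place geographic fixture disks")
        for k in range(n_frames):
            m = np.zeros((n, n), bool)
            for (ci, cj), r in zip(centers, radii):
                m |= _disk(n, ci, cj, r + growth * k)
            frames.append(m)

    elif pattern == "circular":
        k_disks = rng.integers(2, 4)
        # sparse placement: centres far enough apart never to touch
        centers = []
        while len(centers) < k_disks:
            cand = rng.uniform(0.15 * n, 0.85 * n, size=2)
            if all(np.hypot(*(cand - c)) > 0.38 * n for c in centers):
                centers.append(cand)
        r0 = rng.uniform(0.6 * px_per_cm, 0.8 * px_per_cm, size=k_disks)
        growth = rng.uniform(0.4, 0.8)
        for k in range(n_frames):
            m = np.zeros((n, n), bool)
            for (ci, cj), r in zip(centers, r0):
                m |= _disk(n, ci, cj, r + growth * k)
            frames.append(m)

    elif pattern == "dot":
        k_dots = rng.integers(5, 9)
        centers = rng.uniform(0.1 * n, 0.9 * n, size=(k_dots, 2))
        radii = rng.uniform(0.2 * px_per_cm, 0.35 * px_per_cm, size=k_dots)
        if (2 * radii.max() * pixel_size_cm) >= 1.0:
            raise ValueError("dot fixture must stay below 1 cm diameter")
        m = np.zeros((n, n), bool)
        for (ci, cj), r in zip(centers, radii):
            m |= _disk(n, ci, cj, r)
        frames = [m.copy() for _ in range(n_frames)]

    series = [WhealMask(f, pixel_size_cm, time=float(k))
              for k, f in enumerate(frames)]
    # type-defining geometry guards
    if pattern == "circular":
        diam = 2 * r0.min() * pixel_size_cm
        if diam < 1.0:
            raise ValueError("circular fixture requires >= 1 cm disks")
    return series, pattern
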