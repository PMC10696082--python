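"""Morphological classification of wheal masks into the five EGe types.

Eruption geometry (EGe) criteria divide wheals into two classes and five
types:

========  ==============  ==========================================
class     type            defining features
========  ==============  ==========================================
boundary  annular         ring with a single closed arc (KF1)
boundary  broken-annular  ring composed of >= 2 disconnected arcs (KF1+KF2)
area      geographic      filled wheals that fuse while growing (KF3+KF4)
area      circular        isolated filled wheals >= 1 cm, little fusion
area      dot             static wheals < 1 cm in diameter (KF3+KF5)
========  ==============  ==========================================

Five key features are measured on a binary mask series:

* KF1 — boundary score: annularity (hole area / filled area) of the wheal,
  i.e. whether boundary and interior are distinguishable;
* KF2 — boundary disconnectedness: number of arcs composing the ring;
* KF3 — area score: 1 - annularity;
* KF4 — fusion: merge events between snapshots plus relative area growth;
* KF5 — punctate: small (< 1 cm mean diameter) and static over time.

Arcs of one broken ring are disjoint foreground components; they are
re-grouped into a single wheal by a binary closing whose radius sets the
maximal gap treated as a break rather than a separation ("radial gap
detection").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "WhealMask",
    "ComponentInfo",
    "FeatureVector",
    "EruptionLabel",
    "binarize",
    "segment",
    "boundary_structure",
    "track_fusion",
    "punctate_score",
    "measure_features",
    "classify",
    "classify_series",
]

# annularity threshold separating boundary-class from area-class wheals
TAU_ANNULARITY = 0.15
# closing radii tried (px) when grouping broken-ring arcs into one wheal
CLOSING_RADII = (2, 4, 8)
MIN_COMPONENT_PX = 8      # arcs/holes below this are degenerate
COMPONENT_MIN_PX = 4    # floor for area/size statistics (a dot can be tiny)
PUNCTATE_DIAMETER_CM = 1.0
PUNCTATE_GROWTH_EPS = 0.2


@dataclass
class WhealMask:
    """Binary eruption mask with physical pixel size."""

    mask: np.ndarray
    pixel_size_cm: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixel_size_cm <= 0:
            raise ValueError("pixel size must be > 0")


@dataclass
class ComponentInfo:
    label: int
    area_px: int
    filled_area_px: int
    hole_count: int
    hole_area_px: int
    equivalent_diameter_cm: float

    @property
    def annularity(self) -> float:
        return self.hole_area_px / self.filled_area_px


@dataclass
class FeatureVector:
    """The five key-feature scores measured on a mask series."""

    kf1_boundary_score: float       # annularity of the dominant wheal
    kf2_arc_count: float            # arcs per boundary-type wheal (1=closed)
    kf3_area_score: float           # 1 - annularity
    kf4_merge_events: int
    kf4_growth_rate: float          # relative area growth per unit time
    kf5_punctate: bool
    n_components: int
    mean_diameter_cm: float
    max_diameter_cm: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class EruptionLabel:
    class_: str                     # boundary | area
    type_: str                      # annular | broken-annular | geographic | circular | dot
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        boundary_types = {"annular", "broken-annular"}
        if (self.class_ == "boundary") != (self.type_ in boundary_types):
            raise ValueError(f"type {self.type_} inconsistent with class "
                             f"{self.class_}")


def binarize(field_sw: np.ndarray, theta: float = 0.5,
             pixel_size_cm: float = 1.0, time: float = 0.0) -> WhealMask:
    """Threshold an eruption-state field into a wheal mask (``S_w >= theta``)."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    return WhealMask(np.asarray(field_sw) >= theta, pixel_size_cm, time)


def segment(wheal: WhealMask) -> list[ComponentInfo]:
    """Connected components with a per-component hole inventory.

    Foreground uses 8-connectivity and holes (background enclosed by a
    component) 4-connectivity, the standard complementary pair that avoids
    topological paradoxes in hole counting.
    """
    lab = measure.label(wheal.mask, connectivity=2)
    out = []
    for p in measure.regionprops(lab):
        comp = lab == p.label
        filled = ndimage.binary_fill_holes(comp)
        holes = filled & ~comp
        hole_lab, n_holes = ndimage.label(
            holes, structure=ndimage.generate_binary_structure(2, 1))
        out.append(ComponentInfo(
            label=p.label,
            area_px=int(p.area),
            filled_area_px=int(filled.sum()),
            hole_count=int(n_holes),
            hole_area_px=int(holes.sum()),
            equivalent_diameter_cm=2.0 * np.sqrt(p.area / np.pi)
            * wheal.pixel_size_cm,
        ))
    return out


@dataclass
class WhealGroup:
    """One wheal: raw components grouped across radial gaps."""

    annularity: float
    arc_count: int
    filled_area_px: int
    area_px: int


def boundary_structure(wheal: WhealMask,
                       tau_annularity: float = TAU_ANNULARITY,
                       closing_radii: tuple[int, ...] = CLOSING_RADII,
                       min_component_px: int = MIN_COMPONENT_PX,
                       ) -> list[WhealGroup]:
    """Group arcs into wheals and score annularity / arc count (KF1, KF2).

    Closing radii are tried in increasing order; the first radius at which
    some group attains boundary-class annularity (``>= tau``) is kept, so
    that a ring broken into arcs is recognised as one wheal while genuinely
    separate wheals are not merged. A closed ring yields arc count 1;
    degenerate components (< ``min_component_px`` px) are ignored.
    """
    raw = measure.label(wheal.mask, connectivity=2)
    sizes = np.bincount(raw.ravel())
    keep = np.flatnonzero(sizes >= min_component_px)
    keep = keep[keep != 0]
    cleaned = np.isin(raw, keep)
    if not cleaned.any():
        return []

    def groups_at(radius: int) -> list[WhealGroup]:
        closed = ndimage.binary_closing(
            cleaned, structure=morphology.disk(radius),
            border_value=0) if radius else cleaned
        closed_lab = measure.label(closed, connectivity=2)
        groups = []
        for p in measure.regionprops(closed_lab):
            gmask = closed_lab == p.label
            filled = ndimage.binary_fill_holes(gmask)
            holes = int((filled & ~gmask).sum())
            arcs = len([v for v in np.unique(raw[gmask & cleaned]) if v != 0])
            groups.append(WhealGroup(
                annularity=holes / int(filled.sum()),
                arc_count=max(arcs, 1),
                filled_area_px=int(filled.sum()),
                area_px=int((gmask & cleaned).sum()),
            ))
        return groups

    best = groups_at(0)
    if any(g.annularity >= tau_annularity for g in best):
        return best
    for r in closing_radii:
        groups = groups_at(r)
        if any(g.annularity >= tau_annularity for g in groups):
            return groups
    return best


def track_fusion(series: list[WhealMask]) -> tuple[int, float]:
    """Merge events and relative area growth across a mask series (KF4).

    A merge event occurs when two or more components at one snapshot
    overlap a single component at the next. Growth is the relative change
    of total wheal area per unit time over the series. Duplicated frames
    contribute no events.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 snapshots to track fusion")
    shape = series[0].mask.shape
    if any(w.mask.shape != shape for w in series):
        raise ValueError("mask geometry differs across snapshots")

    # growth is meaningful only after the eruption has emerged
    first = next((k for k, w in enumerate(series) if w.mask.any()), 0)
    series = series[first:] if len(series) - first >= 2 else series

    merges = 0
    for a, b in zip(series, series[1:]):
        la = measure.label(a.mask, connectivity=2)
        lb = measure.label(b.mask, connectivity=2)
        for p in measure.regionprops(lb):
            ancestors = np.unique(la[lb == p.label])
            ancestors = ancestors[ancestors != 0]
            if len(ancestors) > 1:
                merges += len(ancestors) - 1

    a0 = series[0].mask.sum()
    a1 = series[-1].mask.sum()
    dt = series[-1].time - series[0].time
    if dt <= 0:
        dt = len(series) - 1  # fall back to frame index spacing
    growth = (a1 - a0) / a0 / dt if a0 else (np.inf if a1 else 0.0)
    return merges, float(growth)


def punctate_score(series: list[WhealMask],
                   size_threshold_cm: float = PUNCTATE_DIAMETER_CM,
                   growth_eps: float = PUNCTATE_GROWTH_EPS) -> bool:
    """KF5: true iff wheals stay small (< 1 cm) and static over the series."""
    if not series:
        raise ValueError("empty mask series")
    last = series[-1]
    comps = [c for c in segment(last) if c.area_px >= COMPONENT_MIN_PX]
    if not comps:
        return False
    mean_diam = float(np.mean([c.equivalent_diameter_cm for c in comps]))
    # judge "no change in size" on the established phase: compare the last
    # frame against the frame two-thirds through the post-emergence series,
    # so the emergence transient does not mask a static wheal
    first = next((k for k, w in enumerate(series) if w.mask.any()), 0)
    ref = first + (len(series) - 1 - first) * 2 // 3
    a0 = series[ref].mask.sum()
    a1 = last.mask.sum()
    rel_change = abs(a1 - a0) / a0 if a0 else (np.inf if a1 else 0.0)
    return mean_diam < size_threshold_cm and rel_change < growth_eps


def measure_features(series: list[WhealMask],
                     tau_annularity: float = TAU_ANNULARITY) -> FeatureVector:
    """Measure KF1–KF5 on the development phase of a mask series.

    The disappearance phase of a wheal is outside the model's scope, so the
    series is truncated at its maximal total wheal area: geometry (KF1–KF3)
    is read from that most-developed frame, and the dynamic features
    (KF4 fusion, KF5 punctate) from the frames up to it.
    """
    if not series:
        raise ValueError("empty mask series")
    areas = [w.mask.sum() for w in series]
    series = series[:int(np.argmax(areas)) + 1]
    last = series[-1]
    warnings: list[str] = []
    comps = [c for c in segment(last) if c.area_px >= COMPONENT_MIN_PX]
    small = [c for c in segment(last) if c.area_px < COMPONENT_MIN_PX]
    if small:
        warnings.append(f"skipped {len(small)} degenerate component(s) < "
                        f"{COMPONENT_MIN_PX} px")

    # Boundary structure is scored over the development frames: an
    # expanding ring keeps a clear hole only while it fits the observed
    # region, so a single late snapshot can miss it. KF1 is the strongest
    # annularity seen; KF2 (disconnection) is read from the latest frame
    # with a qualifying boundary, because a broken-annular wheal is one
    # whose boundary STAYS disconnected as it develops.
    kf1, kf2 = 0.0, 1.0
    for w in series:
        if not w.mask.any():
            continue
        groups = boundary_structure(w, tau_annularity=tau_annularity)
        if not groups:
            continue
        dominant = max(groups, key=lambda g: g.filled_area_px)
        kf1 = max(kf1, dominant.annularity)
        if dominant.annularity >= tau_annularity:
            boundary_groups = [g for g in groups
                               if g.annularity >= tau_annularity]
            kf2 = (float(np.mean([g.arc_count for g in boundary_groups]))
                   if boundary_groups else float(dominant.arc_count))

    if len(series) >= 2:
        merges, growth = track_fusion(series)
    else:
        merges, growth = 0, 0.0
    punctate = punctate_score(series) if comps else False

    return FeatureVector(
        kf1_boundary_score=float(kf1),
        kf2_arc_count=kf2,
        kf3_area_score=float(1.0 - kf1),
        kf4_merge_events=merges,
        kf4_growth_rate=growth,
        kf5_punctate=punctate,
        n_components=len(comps),
        mean_diameter_cm=float(np.mean([c.equivalent_diameter_cm
                                        for c in comps])) if comps else 0.0,
        max_diameter_cm=float(max((c.equivalent_diameter_cm
                                   for c in comps), default=0.0)),
        warnings=warnings,
    )


def classify(fv: FeatureVector,
             tau_annularity: float = TAU_ANNULARITY) -> EruptionLabel:
    """Decision table mapping the key features to an EGe label.

    boundary-class (annularity >= tau): one arc -> annular, several ->
    broken-annular. area-class: fusion (>= 1 merge with positive growth)
    -> geographic; punctate -> dot; otherwise (>= 1 cm wheals) -> circular.
    When fusion and punctate are both set, fusion wins (a warning is
    recorded in the evidence).
    """
    if fv.n_components == 0 and fv.kf1_boundary_score == 0.0:
        raise ValueError("no wheal present: nothing to classify")
    evidence = {
        "kf1": fv.kf1_boundary_score, "kf2": fv.kf2_arc_count,
        "kf3": fv.kf3_area_score, "kf4_merges": fv.kf4_merge_events,
        "kf4_growth": fv.kf4_growth_rate, "kf5": fv.kf5_punctate,
        "mean_diameter_cm": fv.mean_diameter_cm,
        "max_diameter_cm": fv.max_diameter_cm,
    }
    if fv.kf1_boundary_score >= tau_annularity:
        type_ = "annular" if fv.kf2_arc_count < 1.5 else "broken-annular"
        return EruptionLabel("boundary", type_, evidence)

    fusion_high = fv.kf4_merge_events >= 1 and fv.kf4_growth_rate > 0
    if fusion_high and fv.kf5_punctate:
        evidence["warning"] = ("fusion and punctate both set; "
                               "fusion ranks higher")
    if fusion_high:
        return EruptionLabel("area", "geographic", evidence)
    # size separates the non-fusing area types: circular wheals are >= 1 cm
    # (judged on the dominant wheal, so satellite spots do not dominate)
    if fv.kf5_punctate or fv.max_diameter_cm < PUNCTATE_DIAMETER_CM:
        return EruptionLabel("area", "dot", evidence)
    return EruptionLabel("area", "circular", evidence)


def classify_series(series: list[WhealMask],
                    tau_annularity: float = TAU_ANNULARITY) -> EruptionLabel:
    """Measure features on a mask series and classify in one call."""
    return classify(measure_features(series, tau_annularity), tau_annularity)
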