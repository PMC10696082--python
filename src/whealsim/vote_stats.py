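"""Vote-counting reliability statistics for eruption-geometry classification.

A panel of raters (dermatologists) assigns each sample one of the five
eruption-geometry (EGe) types — annular, broken-annular, geographic,
circular, dot — or one of the non-qualifying labels "uniform" / "NA".
The five types group into two classes: boundary (annular, broken-annular)
and area (geographic, circular, dot).

Per-sample reliabilities:

* ``SB`` — fraction of raters selecting the sample's modal qualifying type.
* ``SS`` — fraction of raters whose class AND type both match the modal
  choice; equals the joint probability p(class ∧ type) and never exceeds SB.

Summary level: the classifiable rate at an SB threshold, per-type frequency
tables restricted by an SS threshold, and a one-sided binomial tail P-value
for the classifiable count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EGE_TYPES",
    "NON_QUALIFYING",
    "TYPE_TO_CLASS",
    "VoteMatrix",
    "sb",
    "ss",
    "modal_type",
    "classifiable_summary",
    "binomial_tail_pvalue",
    "frequency_by_type",
]

EGE_TYPES = ("annular", "broken-annular", "geographic", "circular", "dot")
NON_QUALIFYING = ("uniform", "NA")
TYPE_TO_CLASS = {
    "annular": "boundary",
    "broken-annular": "boundary",
    "geographic": "area",
    "circular": "area",
    "dot": "area",
}
_ALL_LABELS = set(EGE_TYPES) | set(NON_QUALIFYING)


@dataclass
class VoteMatrix:
    """Per-sample, per-rater categorical labels.

    ``votes`` is a DataFrame indexed by sample id with one column per rater;
    every cell holds one of the five EGe types or "uniform"/"NA".
    """

    votes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.votes.shape[0] == 0 or self.votes.shape[1] == 0:
            raise ValueError("vote matrix must have >= 1 sample and >= 1 rater")
        bad = set(np.unique(self.votes.to_numpy())) - _ALL_LABELS
        if bad:
            raise ValueError(f"unknown labels in vote matrix: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.votes.shape[0]

    @property
    def n_raters(self) -> int:
        return self.votes.shape[1]

    @classmethod
    def from_csv(cls, path) -> "VoteMatrix":
        """Read a CSV with columns ``sample_id, rater_1..rater_R``."""
        # keep_default_na: the literal label "NA" must stay a string
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "sample_id" not in df.columns:
            raise ValueError("vote CSV must have a 'sample_id' column")
        return cls(df.set_index("sample_id"))

    def to_csv(self, path) -> None:
        self.votes.rename_axis("sample_id").to_csv(path)


def modal_type(sample_votes) -> tuple[str | None, int]:
    """Modal qualifying EGe type of one sample's votes and its count.

    Ties between qualifying types are broken in favour of the type whose
    class gathers more votes overall; a remaining tie yields the first type
    in canonical EGe order and is the caller's cue to flag ambiguity (see
    :func:`frequency_by_type`). Returns ``(None, 0)`` when no rater chose a
    qualifying type.
    """
    votes = list(sample_votes)
    if not votes:
        raise ValueError("empty vote vector")
    counts = Counter(v for v in votes if v in EGE_TYPES)
    if not counts:
        return None, 0
    top = max(counts.values())
    tied = [t for t in EGE_TYPES if counts.get(t, 0) == top]
    if len(tied) == 1:
        return tied[0], top
    class_counts = Counter(TYPE_TO_CLASS[v] for v in votes if v in EGE_TYPES)
    tied.sort(key=lambda t: (-class_counts[TYPE_TO_CLASS[t]], EGE_TYPES.index(t)))
    return tied[0], top


def _is_tied(sample_votes) -> bool:
    counts = Counter(v for v in sample_votes if v in EGE_TYPES)
    if not counts:
        return False
    top = max(counts.values())
    tied = [t for t, c in counts.items() if c == top]
    if len(tied) <= 1:
        return False
    class_counts = Counter(TYPE_TO_CLASS[v] for v in sample_votes if v in EGE_TYPES)
    best = max(class_counts[TYPE_TO_CLASS[t]] for t in tied)
    return sum(1 for t in tied if class_counts[TYPE_TO_CLASS[t]] == best) > 1


def sb(sample_votes) -> float:
    """Type-selection reliability: modal qualifying-type count / rater count."""
    votes = list(sample_votes)
    if not votes:
        raise ValueError("empty vote vector")
    _, count = modal_type(votes)
    return count / len(votes)


def ss(sample_votes) -> float:
    """Joint class-and-type reliability; equals p(class ∧ type) and is ≤ SB."""
    votes = list(sample_votes)
    if not votes:
        raise ValueError("empty vote vector")
    mtype, _ = modal_type(votes)
    if mtype is None:
        return 0.0
    class_counts = Counter(TYPE_TO_CLASS[v] for v in votes if v in EGE_TYPES)
    modal_class = max(class_counts, key=lambda c: (class_counts[c], c))
    joint = sum(
        1 for v in votes
        if v == mtype and TYPE_TO_CLASS[v] == modal_class
    )
    return joint / len(votes)


def reliability_table(matrix: VoteMatrix) -> pd.DataFrame:
    """Per-sample SB, SS, modal type/class and tie flag."""
    rows = []
    for sid, votes in matrix.votes.iterrows():
        v = list(votes)
        mtype, _ = modal_type(v)
        rows.append({
            "sample_id": sid,
            "modal_type": mtype,
            "modal_class": TYPE_TO_CLASS.get(mtype),
            "sb": sb(v),
            "ss": ss(v),
            "tied": _is_tied(v),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def classifiable_summary(matrix: VoteMatrix, sb_threshold: float = 1.0) -> dict:
    """Classifiable / unclassifiable rates at an SB threshold.

    A sample is classifiable when its modal label is a qualifying EGe type
    and its SB reliability reaches the threshold. Returns percentages on the
    0–100 scale.
    """
    table = reliability_table(matrix)
    ok = (table["modal_type"].notna()) & (table["sb"] >= sb_threshold)
    n = len(table)
    # a sample is *positively* unclassifiable when the raters agree, at the
    # same reliability level, that it is uniform / not one of the types
    nq = matrix.votes.isin(NON_QUALIFYING).sum(axis=1) / matrix.n_raters
    return {
        "n_samples": n,
        "sb_threshold": sb_threshold,
        "n_classifiable": int(ok.sum()),
        "classifiable_rate_pct": 100.0 * ok.sum() / n,
        "unclassifiable_rate_pct": 100.0 * (n - ok.sum()) / n,
        "nonqualifying_rate_pct": 100.0 * (nq >= sb_threshold).sum() / n,
    }


def binomial_tail_pvalue(k0: int, n: int, p0: float) -> float:
    """Upper binomial tail ``P(K >= k0)`` for K ~ Binomial(n, p0).

    Used to test whether an observed classifiable count k0 out of n samples
    is consistent with a population classifiable rate of p0. Computed via
    the regularised incomplete beta function (survival function), which is
    stable in log space for large n.
    """
    if not (0 <= k0 <= n):
        raise ValueError("require 0 <= k0 <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("require 0 < p0 < 1")
    if k0 == 0:
        return 1.0
    return float(stats.binom.sf(k0 - 1, n, p0))


def frequency_by_type(matrix: VoteMatrix, ss_threshold: float = 0.0) -> pd.DataFrame:
    """Modal-type frequency table over samples with ``SS > ss_threshold``.

    Samples whose modal type is ambiguous after the class-agreement
    tie-break are excluded (they cannot be assigned a single type); a
    warning column is unnecessary because ties are already flagged in
    :func:`reliability_table`.
    """
    table = reliability_table(matrix)
    sel = table[(table["ss"] > ss_threshold)
                & table["modal_type"].notna()
                & ~table["tied"]]
    counts = sel["modal_type"].value_counts()
    out = pd.DataFrame({
        "type": list(EGE_TYPES),
        "count": [int(counts.get(t, 0)) for t in EGE_TYPES],
    }).set_index("type")
    total = out["count"].sum()
    out["frequency_pct"] = 100.0 * out["count"] / total if total else 0.0
    return out
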