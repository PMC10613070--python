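"""Bias-corrected evenness estimation for TRB repertoires.

Both repertoire summaries used by the downstream models are Pielou evenness
indices,

    J = H / ln S,

with H the bias-corrected Shannon entropy (natural log) of the class
frequencies.  The plug-in entropy is downward-unbiased corrected with the
first-order finite-sample term:

    H = − Σ_i p_i ln p_i − (S − 1) / (2 N),

where p_i = n_i / N, S is the number of classes and N the total number of
sequence copies.  The correction matters at low sequencing depth, where the
plug-in estimate systematically overstates evenness; it is what makes J
comparable across samples whose depths span more than an order of
magnitude.

*Status Diversity* applies the index to the two-class scheme
(productive vs non-productive copy counts; S is fixed at 2).  *Sequence
Diversity* applies it to the clone-size distribution (S = number of unique
clones observed), by convention restricted to productive clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .curation import classify_functionality
from .repertoire import Repertoire


@dataclass(frozen=True)
class CountVector:
    """Class counts feeding an evenness computation.

    ``S`` may exceed the number of non-zero classes when the class scheme
    fixes it (the status scheme always has S = 2, even if one class is
    empty in a given sample).
    """

    counts: np.ndarray
    S: int

    def __init__(self, counts, S: Optional[int] = None):
        arr = np.asarray(counts, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "S", int(S) if S is not None else arr.size)
        if self.S < 1 or self.S < np.count_nonzero(arr):
            raise ValueError(f"invalid class count S={self.S}")
        if self.N < 1:
            raise ValueError("total count N must be >= 1")

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DiversityResult:
    H: float  # corrected entropy, nats, clamped at 0
    J: float  # evenness, clamped to [0, 1]
    S: int
    N: int
    scheme: str
    H_raw: float  # corrected entropy before clamping (diagnostic)

    @property
    def J_raw(self) -> float:
        return self.H_raw / np.log(self.S) if self.S > 1 else np.nan


def shannon_plugin(cv: CountVector) -> float:
    """Plug-in (maximum-likelihood) Shannon entropy in nats."""
    n = cv.counts[cv.counts > 0]
    p = n / cv.N
    return float(-np.sum(p * np.log(p)))


def shannon_basharin(cv: CountVector, clamp: bool = True) -> float:
    """Bias-corrected Shannon entropy: plug-in minus (S − 1) / (2 N).

    Zero-count classes contribute nothing to the entropy sum (0·ln 0 = 0)
    but do enter the correction through S when the scheme fixes S.  The
    correction can push near-degenerate cases below zero; the entropy of a
    distribution is non-negative, so the estimate is clamped at 0 unless
    ``clamp=False``.
    """
    h = shannon_plugin(cv) - (cv.S - 1) / (2.0 * cv.N)
    return max(h, 0.0) if clamp else h


def pielou_index(cv: CountVector) -> float:
    """Evenness J = H / ln S, clamped to [0, 1].  Requires S >= 2."""
    if cv.S < 2:
        raise ValueError("evenness undefined for a single class (S = 1)")
    j = shannon_basharin(cv, clamp=False) / np.log(cv.S)
    return float(min(max(j, 0.0), 1.0))


def _result(cv: CountVector, scheme: str) -> DiversityResult:
    h_raw = shannon_basharin(cv, clamp=False)
    j = pielou_index(cv)
    return DiversityResult(
        H=max(h_raw, 0.0), J=j, S=cv.S, N=cv.N, scheme=scheme, H_raw=h_raw
    )


def status_counts(rep: Repertoire) -> CountVector:
    """Copy counts of productive and non-productive rearrangements (S = 2)."""
    productive = 0
    nonproductive = 0
    for rec in rep.records:
        if classify_functionality(rec) == "productive":
            productive += rec.copy_count
        else:
            nonproductive += rec.copy_count
    return CountVector([productive, nonproductive], S=2)


def status_diversity(rep: Repertoire) -> DiversityResult:
    """Evenness of the productive vs non-productive copy split.

    Low values mean productive copies dominate, i.e. lymphocytes carrying a
    first-attempt productive rearrangement (germ-line second allele) have
    expanded relative to those carrying an additional non-productive one.
    Every copy of every unique rearrangement counts.
    """
    if rep.total_copies == 0:
        raise ValueError(f"repertoire {rep.sample_id!r} has zero total copies")
    return _result(status_counts(rep), scheme="status")


def sequence_diversity(rep: Repertoire, productive_only: bool = True) -> DiversityResult:
    """Evenness of the clone-size distribution (S = number of clones).

    Expects a curated, clone-collapsed repertoire.  Low values indicate a
    more clonal repertoire (a few clones hold most copies).  The default
    restricts to productive clones, the convention used for all reported
    clonality models.
    """
    records = rep.records
    if productive_only:
        records = [r for r in records if classify_functionality(r) == "productive"]
    counts = [r.copy_count for r in records]
    if len(counts) < 2:
        raise ValueError(
            f"repertoire {rep.sample_id!r} has fewer than 2 clones; evenness undefined"
        )
    return _result(CountVector(counts), scheme="sequence")


def cohort_diversity_table(cohort: list[Repertoire]) -> pd.DataFrame:
    """Tidy per-sample diversity table feeding the regression models.

    Columns: sample_id, donor_id, age, sex, compartment, timepoint, N, S,
    status_J, sequence_J.  N (total curated copies) doubles as the
    regression weight.
    """
    rows = []
    for rep in cohort:
        st = status_diversity(rep)
        sq = sequence_diversity(rep)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "donor_id": rep.donor_id,
                "age": rep.age,
                "sex": rep.sex.value if rep.sex else None,
                "compartment": rep.compartment.value,
                "timepoint": rep.timepoint,
                "N": rep.total_copies,
                "S": sq.S,
                "status_J": st.J,
                "sequence_J": sq.J,
            }
        )
    return pd.DataFrame(rows)
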