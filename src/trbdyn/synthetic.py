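"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at the level the models consume, what deep TRB
sequencing of blood delivers:

- per-sample sequencing depth drawn log-uniformly over a configurable
  range (half a million to eight million copies by default);
- a productive/non-productive copy split whose evenness (Status Diversity)
  follows a piecewise-linear age trend with optional sex-specific terms
  plus a Gaussian per-donor effect — the target evenness is inverted
  numerically to a productive-copy fraction, and the realized counts are a
  binomial draw at the sample's depth;
- a heavy-tailed (discretized power-law) clone-size distribution whose
  exponent is chosen, again by numerical inversion, so that clone-size
  evenness (Sequence Diversity) follows its own embedded age trend;
- optional contaminant records violating each curation rule (orphon V,
  unresolved calls, indexing errors, non-functional genes, the excluded
  gene) at configurable copy-fraction rates;
- a longitudinal design of six donors (three men, three women) sampled at
  three timepoints a decade apart, as sorted CD4/CD8 pairs with a known
  blood ratio.

Every embedded coefficient is returned in a truth record so that the
fitting modules can be tested for parameter recovery.  Generation is
seed-deterministic end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .diversity import CountVector, pielou_index
from .genes import GeneReference, default_reference
from .repertoire import (
    Compartment,
    FrameStatus,
    RearrangementRecord,
    Repertoire,
    Sex,
    UNRESOLVED,
)

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# evenness inversions


def two_class_evenness(p: float) -> float:
    """Plug-in Pielou J of a two-class split with majority fraction p."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    q = 1.0 - p
    return float(-(p * np.log(p) + q * np.log(q)) / _LN2)


def productive_fraction_for_status_j(target_j: float, tol: float = 1e-10) -> float:
    """Invert J -> productive copy fraction on the p >= 1/2 branch.

    The age/sex models are linear on the evenness scale, so the generator
    works on J and converts to a binomial success probability by bisection
    (two_class_evenness is strictly decreasing on [1/2, 1]).
    """
    if not (0.0 < target_j < 1.0):
        raise ValueError(f"target status J must lie in (0, 1), got {target_j}")
    lo, hi = 0.5, 1.0 - 1e-15
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if two_class_evenness(mid) > target_j:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def powerlaw_weights(n_clones: int, exponent: float) -> np.ndarray:
    """Normalized Zipf-like clone-size law: w_i ∝ i^(−exponent)."""
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    w = np.arange(1, n_clones + 1, dtype=float) ** (-float(exponent))
    return w / w.sum()


def law_evenness(n_clones: int, exponent: float) -> float:
    """Pielou J of the power law itself (infinite-depth limit)."""
    w = powerlaw_weights(n_clones, exponent)
    return float(-(w * np.log(w)).sum() / np.log(n_clones))


_exponent_grids: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def exponent_for_sequence_j(target_j: float, n_clones: int) -> float:
    """Invert J -> power-law exponent via a cached monotone grid."""
    if n_clones not in _exponent_grids:
        s_grid = np.linspace(0.0, 2.0, 201)
        j_grid = np.array([law_evenness(n_clones, s) for s in s_grid])
        _exponent_grids[n_clones] = (s_grid, j_grid)
    s_grid, j_grid = _exponent_grids[n_clones]
    if not (j_grid[-1] <= target_j <= 1.0):
        raise ValueError(
            f"target sequence J={target_j} not achievable with {n_clones} clones "
            f"(range [{j_grid[-1]:.3f}, 1])"
        )
    # j_grid decreases in s; interpolate on the reversed axis
    return float(np.interp(target_j, j_grid[::-1], s_grid[::-1]))


# ---------------------------------------------------------------------------
# single-repertoire synthesis

#: default contaminant copy fractions, shaped like the observed filtration
#: shares of vendor whole-blood exports (unresolved V calls dominate)
DEFAULT_CONTAMINATION = {
    "orphon_v": 0.0001,
    "unresolved_v": 0.22,
    "unresolved_j": 0.0004,
    "indexing_error": 0.0017,
    "nonfunctional_or_orf_gene": 0.032,
    "excluded_gene": 0.00002,
}

_NONFUNCTIONAL_V = "TRBV23-01"  # valid locus name outside the functional set
_ORPHON_V = "TRBV21/OR9-2"

_BASES = np.array(list("ACGT"))


def _clone_sequences(n: int, rng: np.random.Generator, tag: str, length: int = 48) -> list[str]:
    """Unique random nucleotide sequences (uniqueness via an encoded suffix)."""
    prefix = rng.integers(0, 4, size=(n, length - 12))
    seqs = []
    for i in range(n):
        suffix = np.base_repr(i, base=4).zfill(10)
        body = "".join(_BASES[prefix[i]])
        encoded = "".join("ACGT"[int(c)] for c in suffix)
        seqs.append(body + tag + encoded)
    return seqs


def simulate_repertoire(
    depth: int = 600_000,
    productive_fraction: float = 0.84,
    sequence_exponent: float = 0.57,
    n_clones: int = 300,
    contamination: Optional[dict[str, float]] = None,
    seed: int | np.random.Generator = 0,
    ref: Optional[GeneReference] = None,
    sample_id: str = "synthetic",
    **metadata,
) -> Repertoire:
    """Generate one repertoire with known evenness structure.

    ``depth`` clean (curation-surviving) copies are split binomially into
    productive and non-productive pools; each pool's clone sizes follow a
    discretized power law with the given exponent.  ``contamination`` maps
    curation categories to target copy fractions of the *pre-curation*
    total; contaminant records are constructed to violate exactly their own
    rule.

    The defaults describe the coverage-study repertoire: 6×10^5 copies,
    a productive copy fraction of 0.84 (status evenness ≈ 0.63) and a
    300-clone law with exponent 0.57 (sequence evenness ≈ 0.95).  The
    richness default is deliberately coarse: the shallowest study coverage
    (10^4 copies) then still samples every clone ~30 times on average,
    the regime in which evenness estimates are comparable across depths.
    Cohort-level generators pass their own, richer clone laws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not (0.0 < productive_fraction < 1.0):
        raise ValueError("productive_fraction must be in (0, 1)")
    if ref is None:
        ref = default_reference()
    usable_v = sorted(ref.functional_v - ref.excluded)
    usable_j = sorted(ref.functional_j)
    usable_d = sorted(ref.functional_d) or [""]

    n_prod = int(rng.binomial(depth, productive_fraction))
    n_prod = min(max(n_prod, 2), depth - 2)
    n_nonprod = depth - n_prod

    s_np = max(2, int(round(n_clones * (1.0 - productive_fraction) / productive_fraction)))
    pools = [
        ("P", n_prod, n_clones, FrameStatus.IN_FRAME),
        ("N", n_nonprod, s_np, None),  # frame drawn per clone below
    ]
    records: list[RearrangementRecord] = []
    for tag, copies, pool_clones, frame in pools:
        counts = rng.multinomial(copies, powerlaw_weights(pool_clones, sequence_exponent))
        keep = np.nonzero(counts)[0]
        seqs = _clone_sequences(len(keep), rng, tag)
        v_idx = rng.integers(0, len(usable_v), size=len(keep))
        j_idx = rng.integers(0, len(usable_j), size=len(keep))
        d_idx = rng.integers(0, len(usable_d), size=len(keep))
        frames = (
            np.full(len(keep), 0)
            if frame is FrameStatus.IN_FRAME
            else rng.integers(1, 3, size=len(keep))
        )
        frame_map = {0: FrameStatus.IN_FRAME, 1: FrameStatus.OUT_OF_FRAME, 2: FrameStatus.STOP_CODON}
        for pos, clone in enumerate(keep):
            records.append(
                RearrangementRecord(
                    nucleotide=seqs[pos],
                    copy_count=int(counts[clone]),
                    v_call=usable_v[v_idx[pos]],
                    d_call=usable_d[d_idx[pos]],
                    j_call=usable_j[j_idx[pos]],
                    frame_status=frame_map[int(frames[pos])],
                    cdr3_start=30,
                    n2_start=39,
                )
            )

    if contamination:
        bad_total = sum(contamination.values())
        if bad_total >= 0.9:
            raise ValueError("contamination fractions sum to >= 0.9")
        pre_curation_total = int(round(depth / (1.0 - bad_total)))
        builders = {
            "orphon_v": dict(v_call=_ORPHON_V),
            "unresolved_v": dict(v_call=UNRESOLVED),
            "unresolved_j": dict(j_call=UNRESOLVED),
            "indexing_error": dict(cdr3_start=30, n2_start=20),
            "nonfunctional_or_orf_gene": dict(v_call=_NONFUNCTIONAL_V),
            "excluded_gene": dict(v_call="TRBV03-01"),
        }
        for ci, (category, fraction) in enumerate(sorted(contamination.items())):
            if fraction <= 0:
                continue
            if category not in builders:
                raise ValueError(f"unknown contamination category {category!r}")
            n_copies = int(rng.binomial(pre_curation_total, fraction))
            if n_copies == 0:
                continue
            n_bad_clones = max(1, n_copies // 100)
            counts = rng.multinomial(n_copies, np.full(n_bad_clones, 1.0 / n_bad_clones))
            seqs = _clone_sequences(n_bad_clones, rng, f"X{ci}")
            overrides = builders[category]
            for pos in np.nonzero(counts)[0]:
                fields = dict(
                    nucleotide=seqs[pos],
                    copy_count=int(counts[pos]),
                    v_call=usable_v[int(rng.integers(0, len(usable_v)))],
                    d_call="",
                    j_call=usable_j[int(rng.integers(0, len(usable_j)))],
                    frame_status=FrameStatus.IN_FRAME
                    if rng.random() < 0.5
                    else FrameStatus.OUT_OF_FRAME,
                    cdr3_start=30,
                    n2_start=39,
                )
                fields.update(overrides)
                records.append(RearrangementRecord(**fields))

    return Repertoire(sample_id=sample_id, records=records, **metadata)


# ---------------------------------------------------------------------------
# cross-sectional cohorts


@dataclass
class StatusLaw:
    """Two-segment age trend of Status Diversity.

    Donors up to the breakpoint age follow one line, older donors another
    (segments need not join: each segment has its own intercept and slope,
    exactly the form the piecewise regression fits).  ``breakpoint=None``
    degenerates to the single young line over all ages.
    """

    intercept_young: float = 0.6817
    slope_young: float = -0.0060
    intercept_old: float = 0.6227
    slope_old: float = -0.0003
    breakpoint: Optional[int] = 18
    sex_offset: float = 0.0  # added to the intercept for women
    sex_slope_offset: float = 0.0  # added to both slopes for women

    def mean(self, age: np.ndarray, female: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        female = np.asarray(female, dtype=float)
        slope_y = self.slope_young + self.sex_slope_offset * female
        slope_o = self.slope_old + self.sex_slope_offset * female
        if self.breakpoint is None:
            out = self.intercept_young + slope_y * age
        else:
            out = np.where(
                age <= self.breakpoint,
                self.intercept_young + slope_y * age,
                self.intercept_old + slope_o * age,
            )
        return out + self.sex_offset * female


@dataclass
class SequenceLaw:
    """Linear age trend of Sequence Diversity (clone-size evenness)."""

    intercept: float = 0.9519
    slope: float = -0.0014
    sex_offset: float = 0.0

    def mean(self, age: np.ndarray, female: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + self.slope * np.asarray(age, dtype=float)
            + self.sex_offset * np.asarray(female, dtype=float)
        )


@dataclass
class CohortParams:
    """Study conditions for a cross-sectional synthetic cohort."""

    n_donors: int = 487
    age_min: int = 1
    age_max: int = 74
    female_fraction: float = 0.47
    depth_range: tuple[int, int] = (500_000, 8_000_000)
    n_clones: int = 20_000
    status: StatusLaw = field(default_factory=StatusLaw)
    sequence: SequenceLaw = field(default_factory=SequenceLaw)
    donor_sd_status: float = 0.025
    donor_sd_sequence: float = 0.03
    contamination: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.depth_range[0] < 1_000:
            raise ValueError("minimum depth is 1000 copies")


@dataclass
class CohortTruth:
    """Everything the generator embedded, for recovery tests."""

    params: CohortParams
    donor_table: pd.DataFrame  # age, sex, depth, target status/sequence J


def _draw_cohort_frame(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_donors
    ages = rng.integers(params.age_min, params.age_max + 1, size=n)
    female = rng.random(n) < params.female_fraction
    depths = np.exp(
        rng.uniform(np.log(params.depth_range[0]), np.log(params.depth_range[1]), size=n)
    ).astype(np.int64)
    status_mu = params.status.mean(ages, female)
    sequence_mu = params.sequence.mean(ages, female)
    status_target = np.clip(
        status_mu + rng.normal(0.0, params.donor_sd_status, size=n), 0.02, 0.98
    )
    sequence_target = np.clip(
        sequence_mu + rng.normal(0.0, params.donor_sd_sequence, size=n), 0.55, 0.995
    )
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "donor_id": [f"D{i:04d}" for i in range(n)],
            "age": ages,
            "sex": np.where(female, "female", "male"),
            "depth": depths,
            "status_J_target": status_target,
            "sequence_J_target": sequence_target,
        }
    )


def _realize_table_row(
    depth: int,
    status_target: float,
    sequence_target: float,
    n_clones: int,
    rng: np.random.Generator,
) -> tuple[float, float, int]:
    """Sample realized evenness values at the given depth.

    Status: binomial draw of productive copies.  Sequence: multinomial
    clone sizes under the inverted power law; the realized index uses the
    observed clone count, exactly as the estimator would on real records.
    """
    p = productive_fraction_for_status_j(status_target)
    k = int(rng.binomial(depth, p))
    k = min(max(k, 1), depth - 1)
    status_j = pielou_index(CountVector([k, depth - k], S=2))

    s = exponent_for_sequence_j(sequence_target, n_clones)
    counts = rng.multinomial(k, powerlaw_weights(n_clones, s))
    counts = counts[counts > 0]
    seq_j = pielou_index(CountVector(counts))
    return status_j, seq_j, k


def simulate_cohort(
    params: Optional[CohortParams] = None,
    seed: int = 0,
    level: str = "table",
) -> tuple[object, CohortTruth]:
    """Generate a cross-sectional cohort.

    ``level="table"`` returns the per-sample diversity table (columns
    ``age, sex, N, status_J, sequence_J``) obtained by actually sampling
    copy counts at each sample's depth — the input the regression module
    consumes.  ``level="repertoire"`` additionally materializes full
    record-level repertoires (use modest depths for this).
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    frame = _draw_cohort_frame(params, rng)
    truth = CohortTruth(params=params, donor_table=frame.copy())

    if level == "table":
        status_j = np.empty(len(frame))
        seq_j = np.empty(len(frame))
        for i, row in enumerate(frame.itertuples()):
            status_j[i], seq_j[i], _ = _realize_table_row(
                int(row.depth),
                float(row.status_J_target),
                float(row.sequence_J_target),
                params.n_clones,
                rng,
            )
        table = frame[["sample_id", "donor_id", "age", "sex"]].copy()
        table["N"] = frame["depth"]
        table["status_J"] = status_j
        table["sequence_J"] = seq_j
        return table, truth

    if level == "repertoire":
        reps = []
        for row in frame.itertuples():
            p = productive_fraction_for_status_j(float(row.status_J_target))
            s = exponent_for_sequence_j(float(row.sequence_J_target), params.n_clones)
            reps.append(
                simulate_repertoire(
                    depth=int(row.depth),
                    productive_fraction=p,
                    sequence_exponent=s,
                    n_clones=params.n_clones,
                    contamination=params.contamination,
                    seed=rng,
                    sample_id=row.sample_id,
                    donor_id=row.donor_id,
                    age=int(row.age),
                    sex=Sex(row.sex),
                )
            )
        return reps, truth

    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# longitudinal designs


@dataclass
class LongitudinalCoefs:
    """Fixed effects to embed: J = b0 + b1·AGE + b2·SEX + b3·AGE·SEX
    (+ b4·AGE·CELLTYPE for sorted-compartment designs)."""

    b0: float
    b1: float
    b2: float
    b3: float = 0.0
    b4: float = 0.0

    def mean(self, age, female, cd8=0.0):
        age = np.asarray(age, dtype=float)
        female = np.asarray(female, dtype=float)
        cd8 = np.asarray(cd8, dtype=float)
        return (
            self.b0
            + self.b1 * age
            + self.b2 * female
            + self.b3 * age * female
            + self.b4 * age * cd8
        )


@dataclass
class LongitudinalParams:
    """Six-donor, three-timepoint sorted-compartment design."""

    n_donors_per_sex: int = 3
    n_timepoints: int = 3
    years_between: int = 10
    start_age_range: tuple[int, int] = (24, 45)
    status: LongitudinalCoefs = field(
        default_factory=lambda: LongitudinalCoefs(0.5823, 0.0004, 0.0829, -0.0011)
    )
    sequence: LongitudinalCoefs = field(
        default_factory=lambda: LongitudinalCoefs(0.9597, -0.0008, -0.0698, 0.0)
    )
    donor_sd_status: float = 0.04
    donor_sd_sequence: float = 0.025
    celltype_sd_status: float = 0.02
    celltype_sd_sequence: float = 0.05
    resid_sd: float = 0.005
    depth: int = 200_000
    n_clones: int = 5_000
    ratio_log_sd: float = 0.25  # CD4/CD8 blood ratio ~ lognormal around 2

    @property
    def n_donors(self) -> int:
        return 2 * self.n_donors_per_sex


@dataclass
class LongitudinalTruth:
    params: LongitudinalParams
    donor_effects: pd.DataFrame  # donor, sex, status/sequence intercept + CD8 offsets
    design: pd.DataFrame  # donor, sex, timepoint, age, ratio


def _longitudinal_design(
    params: LongitudinalParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    donors, sexes = [], []
    for i in range(1, params.n_donors + 1):
        donors.append(str(i))
        sexes.append("male" if i <= params.n_donors_per_sex else "female")
    effects = pd.DataFrame(
        {
            "donor": donors,
            "sex": sexes,
            "status_offset": rng.normal(0, params.donor_sd_status, len(donors)),
            "sequence_offset": rng.normal(0, params.donor_sd_sequence, len(donors)),
            "status_cd8_offset": rng.normal(0, params.celltype_sd_status, len(donors)),
            "sequence_cd8_offset": rng.normal(
                0, params.celltype_sd_sequence, len(donors)
            ),
        }
    )
    rows = []
    start_ages = rng.integers(
        params.start_age_range[0], params.start_age_range[1] + 1, size=len(donors)
    )
    for d, sex, a0 in zip(donors, sexes, start_ages):
        for t in range(params.n_timepoints):
            rows.append(
                {
                    "donor": d,
                    "sex": sex,
                    "timepoint": t,
                    "age": int(a0 + t * params.years_between),
                    "ratio": float(
                        np.clip(2.0 * np.exp(rng.normal(0, params.ratio_log_sd)), 0.5, 5.0)
                    ),
                }
            )
    return effects, pd.DataFrame(rows)


def simulate_longitudinal(
    params: Optional[LongitudinalParams] = None,
    seed: int = 0,
    level: str = "table",
    by_celltype: bool = False,
) -> tuple[object, LongitudinalTruth]:
    """Generate a longitudinal design.

    ``level="table"``: realized diversity table, one row per donor-timepoint
    (whole-blood) or per donor-timepoint-compartment (``by_celltype=True``),
    with sampling performed at ``params.depth``.  ``level="repertoire"``:
    sorted CD4/CD8 :class:`Repertoire` pairs per donor-timepoint, whose
    reconstituted merge follows the embedded whole-blood model.
    """
    params = params or LongitudinalParams()
    rng = np.random.default_rng(seed)
    effects, design = _longitudinal_design(params, rng)
    truth = LongitudinalTruth(params=params, donor_effects=effects, design=design)
    eff = effects.set_index("donor")

    def targets(row, cd8: float) -> tuple[float, float]:
        female = 1.0 if row.sex == "female" else 0.0
        st = (
            params.status.mean(row.age, female, cd8)
            + eff.loc[row.donor, "status_offset"]
            + cd8 * eff.loc[row.donor, "status_cd8_offset"]
            + rng.normal(0, params.resid_sd)
        )
        sq = (
            params.sequence.mean(row.age, female, cd8)
            + eff.loc[row.donor, "sequence_offset"]
            + cd8 * eff.loc[row.donor, "sequence_cd8_offset"]
            + rng.normal(0, params.resid_sd)
        )
        return float(np.clip(st, 0.02, 0.98)), float(np.clip(sq, 0.55, 0.995))

    if level == "table":
        rows = []
        celltypes = ["CD4", "CD8"] if by_celltype else [None]
        for row in design.itertuples():
            for ct in celltypes:
                cd8 = 1.0 if ct == "CD8" else 0.0
                st_t, sq_t = targets(row, cd8)
                st, sq, _ = _realize_table_row(
                    params.depth, st_t, sq_t, params.n_clones, rng
                )
                out = {
                    "donor": row.donor,
                    "sex": row.sex,
                    "timepoint": row.timepoint,
                    "age": row.age,
                    "N": params.depth,
                    "status_J": st,
                    "sequence_J": sq,
                }
                if ct is not None:
                    out["celltype"] = ct
                rows.append(out)
        return pd.DataFrame(rows), truth

    if level == "repertoire":
        pairs = []
        for row in design.itertuples():
            comp_reps = {}
            for ct, comp in (("CD4", Compartment.CD4), ("CD8", Compartment.CD8)):
                cd8 = 1.0 if ct == "CD8" else 0.0
                st_t, sq_t = targets(row, cd8)
                p = productive_fraction_for_status_j(st_t)
                s = exponent_for_sequence_j(sq_t, params.n_clones)
                comp_reps[ct] = simulate_repertoire(
                    depth=params.depth,
                    productive_fraction=p,
                    sequence_exponent=s,
                    n_clones=params.n_clones,
                    seed=rng,
                    sample_id=f"{row.donor}_t{row.timepoint}_{ct}",
                    donor_id=row.donor,
                    age=int(row.age),
                    sex=Sex(row.sex),
                    compartment=comp,
                    timepoint=int(row.timepoint),
                    cd4_cd8_ratio=row.ratio,
                )
            pairs.append((comp_reps["CD4"], comp_reps["CD8"]))
        return pairs, truth

    raise ValueError(f"unknown level {level!r}")
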