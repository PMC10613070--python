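"""Monte-Carlo resampling of repertoires.

Two procedures, both drawing *without replacement* from the finite observed
copy pool (multivariate hypergeometric over clones), both repeated a
configurable number of times (default 100) with averaged diversity outputs:

- **Depth subsampling** — every repertoire is subsampled to a fixed list of
  coverages so that evenness estimates can be compared across samples whose
  native depths differ by more than an order of magnitude.  Samples
  shallower than a target depth are skipped at that depth and recorded.

- **Whole-blood reconstitution** — sorted CD4 and CD8 sub-repertoires of a
  donor are merged in the proportion dictated by the donor's blood CD4/CD8
  ratio r: the overrepresented compartment is downsampled to the expected
  copy count and the merged repertoire has CD4 copy fraction r/(1+r) up to
  integer rounding.

Replicate RNG streams are spawned from one master seed, so every output is
bit-reproducible given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import sequence_diversity, status_diversity
from .genes import GeneReference
from .repertoire import Compartment, Repertoire, collapse_clones

#: fixed coverages of the sequencing-depth study
DEFAULT_DEPTHS = (10_000, 80_000, 150_000, 500_000, 1_000_000, 2_000_000, 4_000_000)

DEFAULT_REPLICATES = 100


def subsample_to_depth(
    rep: Repertoire, depth: int, rng: np.random.Generator | int
) -> Repertoire:
    """Draw exactly ``depth`` copies without replacement from the copy pool.

    Clone counts follow the multivariate hypergeometric distribution; clones
    drawn to zero copies disappear.  Metadata is preserved.  ``depth`` equal
    to the total copy count returns the repertoire unchanged (identity).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    total = rep.total_copies
    if depth < 1:
        raise ValueError(f"depth must be positive, got {depth}")
    if depth > total:
        raise ValueError(
            f"depth {depth} exceeds total copies {total} of sample {rep.sample_id!r}; "
            "pre-filter samples below the target coverage"
        )
    if depth == total:
        return rep.with_records(rep.records)
    counts = rep.copy_counts()
    drawn = rng.multivariate_hypergeometric(counts, depth, method="marginals")
    records = [
        replace(rec, copy_count=int(k))
        for rec, k in zip(rep.records, drawn)
        if k > 0
    ]
    return rep.with_records(records)


@dataclass
class DepthProfile:
    """Replicate-averaged diversities at each target coverage."""

    depths: list[int]
    n_replicates: int
    seed: int
    table: pd.DataFrame  # columns: depth, status_J_mean/sd, sequence_J_mean/sd, n_replicates
    skipped_depths: list[int] = field(default_factory=list)


def depth_profile(
    rep: Repertoire,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> DepthProfile:
    """Mean and SD of both evenness indices over replicate subsamplings.

    ``depths`` must be ascending.  Depths exceeding the sample's total
    copies are skipped and listed in ``skipped_depths``, mirroring the fact
    that only a fraction of samples reaches the deepest coverages.
    """
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    master = np.random.default_rng(seed)
    rows = []
    skipped = []
    total = rep.total_copies
    for depth in depths:
        if depth > total:
            skipped.append(depth)
            continue
        status_vals = np.empty(n_replicates)
        seq_vals = np.empty(n_replicates)
        streams = master.spawn(n_replicates)
        for k, stream in enumerate(streams):
            sub = subsample_to_depth(rep, depth, stream)
            sub = collapse_clones(sub)
            status_vals[k] = status_diversity(sub).J
            seq_vals[k] = sequence_diversity(sub).J
        rows.append(
            {
                "depth": depth,
                "status_J_mean": status_vals.mean(),
                "status_J_sd": status_vals.std(ddof=1) if n_replicates > 1 else 0.0,
                "sequence_J_mean": seq_vals.mean(),
                "sequence_J_sd": seq_vals.std(ddof=1) if n_replicates > 1 else 0.0,
                "n_replicates": n_replicates,
            }
        )
    return DepthProfile(
        depths=depths,
        n_replicates=n_replicates,
        seed=seed,
        table=pd.DataFrame(rows),
        skipped_depths=skipped,
    )


@dataclass(frozen=True)
class MergePlan:
    """Expected copy draws for merging CD4/CD8 at blood ratio r."""

    n_cd4: int
    n_cd8: int
    ratio: float
    draw_cd4: int  # copies to draw from the CD4 compartment
    draw_cd8: int
    overrepresented: str  # "CD4", "CD8" or "balanced"

    @property
    def cd4_fraction(self) -> float:
        return self.draw_cd4 / (self.draw_cd4 + self.draw_cd8)

    @property
    def target_fraction(self) -> float:
        return self.ratio / (1.0 + self.ratio)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def plan_merge(n_cd4: int, n_cd8: int, ratio: float) -> MergePlan:
    """Decide how many copies to draw from each compartment.

    If the observed copy ratio n_cd4/n_cd8 exceeds the blood ratio r, CD4
    is overrepresented: draw round(r · n_cd8) copies from CD4 and keep all
    of CD8; otherwise draw round(n_cd4 / r) from CD8 and keep all of CD4.
    Either way the merged CD4 copy fraction equals r/(1+r) up to rounding
    (nearest integer, ties to even).
    """
    if ratio <= 0:
        raise ValueError(f"CD4/CD8 ratio must be positive, got {ratio}")
    if n_cd4 < 1 or n_cd8 < 1:
        raise ValueError("both compartments must have at least one copy")
    observed = n_cd4 / n_cd8
    if observed > ratio:
        return MergePlan(
            n_cd4, n_cd8, ratio, _round_half_even(ratio * n_cd8), n_cd8, "CD4"
        )
    if observed < ratio:
        return MergePlan(
            n_cd4, n_cd8, ratio, n_cd4, _round_half_even(n_cd4 / ratio), "CD8"
        )
    return MergePlan(n_cd4, n_cd8, ratio, n_cd4, n_cd8, "balanced")


@dataclass
class ReconstitutionResult:
    """Replicate-averaged diversities of the reconstituted whole-blood sample."""

    status_J: float
    sequence_J: float
    status_J_sd: float
    sequence_J_sd: float
    n_replicates: int
    seed: int
    plan: MergePlan
    representative: Repertoire  # merged repertoire from the first replicate


def reconstitute_whole_blood(
    cd4: Repertoire,
    cd8: Repertoire,
    ratio: Optional[float] = None,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    ref: Optional[GeneReference] = None,
) -> ReconstitutionResult:
    """Merge sorted CD4/CD8 repertoires into a whole-blood estimate.

    Each replicate: plan the draw from the blood ratio, downsample the
    overrepresented compartment without replacement, concatenate, collapse
    clones (re-running sequence curation when ``ref`` is given) and compute
    both evenness indices.  The final estimates are the replicate means.
    """
    if cd4.donor_id != cd8.donor_id or cd4.timepoint != cd8.timepoint:
        raise ValueError(
            f"compartments are not paired: {cd4.donor_id}/t{cd4.timepoint} vs "
            f"{cd8.donor_id}/t{cd8.timepoint}"
        )
    if ratio is None:
        ratio = cd4.cd4_cd8_ratio or cd8.cd4_cd8_ratio
    if ratio is None:
        raise ValueError("no CD4/CD8 ratio available")

    plan = plan_merge(cd4.total_copies, cd8.total_copies, ratio)
    master = np.random.default_rng(seed)
    status_vals = np.empty(n_replicates)
    seq_vals = np.empty(n_replicates)
    representative: Optional[Repertoire] = None
    def take(rep: Repertoire, n_draw: int, total: int, stream) -> Repertoire:
        if n_draw == total:
            return rep
        if n_draw == 0:  # extreme ratio: the other compartment dominates fully
            return rep.with_records([])
        return subsample_to_depth(rep, n_draw, stream)

    for k, stream in enumerate(master.spawn(n_replicates)):
        part4 = take(cd4, plan.draw_cd4, plan.n_cd4, stream)
        part8 = take(cd8, plan.draw_cd8, plan.n_cd8, stream)
        merged = Repertoire(
            sample_id=f"{cd4.donor_id}_t{cd4.timepoint}_wb",
            records=list(part4.records) + list(part8.records),
            donor_id=cd4.donor_id,
            age=cd4.age,
            sex=cd4.sex,
            compartment=Compartment.WHOLE_BLOOD,
            timepoint=cd4.timepoint,
            cd4_cd8_ratio=ratio,
        )
        if ref is not None:
            from .curation import curate_records

            merged, _ = curate_records(merged, ref)
        merged = collapse_clones(merged)
        status_vals[k] = status_diversity(merged).J
        seq_vals[k] = sequence_diversity(merged).J
        if representative is None:
            representative = merged
    return ReconstitutionResult(
        status_J=float(status_vals.mean()),
        sequence_J=float(seq_vals.mean()),
        status_J_sd=float(status_vals.std(ddof=1)) if n_replicates > 1 else 0.0,
        sequence_J_sd=float(seq_vals.std(ddof=1)) if n_replicates > 1 else 0.0,
        n_replicates=n_replicates,
        seed=seed,
        plan=plan,
        representative=representative,
    )
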