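"""End-to-end orchestration: curate → diversity → (resample) → model.

A run is driven by a single YAML config (see :class:`RunConfig`), writes
tidy TSV tables plus JSON metadata into the output directory, and records a
provenance block (config hash, seeds, package version) sufficient to
reproduce every output bit-exactly.  The diversity stage — the slow one
when depth profiling is on — is cached on disk keyed by the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .curation import curate_cohort, curate_records
from .diversity import cohort_diversity_table, sequence_diversity, status_diversity
from .genes import GeneReference, default_reference
from .io import read_manifest
from .mixed import (
    GROUP_DONOR,
    GROUP_DONOR_CELLTYPE,
    MixedSpec,
    CoefficientTable,
    icc,
    lrt_backward_select,
    slope_for_group,
    summarize_initial_diversity,
)
from .regression import cross_sectional_table
from .repertoire import Compartment, Repertoire, collapse_clones
from .resampling import DEFAULT_DEPTHS, depth_profile, reconstitute_whole_blood


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str
    output_dir: str = "trbdyn_out"
    gene_reference: Optional[str] = None  # None = bundled snapshot
    outlier_screen: bool = True
    outlier_alpha: float = 0.007
    depth_profile: bool = False
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    piecewise: bool = True
    min_group: int = 5
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.depths = tuple(self.depths)
        if list(self.depths) != sorted(self.depths):
            raise ValueError("depths must be ascending")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "trbdyn",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
    }


def _load_reference(config: RunConfig) -> GeneReference:
    if config.gene_reference:
        return GeneReference.from_json(config.gene_reference)
    return default_reference()


def _curated_diversity(
    config: RunConfig, cohort: list[Repertoire], out: Path
) -> tuple[pd.DataFrame, dict]:
    """Curate the cohort and compute the per-sample diversity table, cached
    on disk keyed by the config hash."""
    cache = out / "cache" / f"diversity_{config.digest()}.tsv"
    report_path = out / "cache" / f"curation_{config.digest()}.json"
    if cache.exists() and report_path.exists():
        return pd.read_csv(cache, sep="\t"), json.loads(report_path.read_text())
    ref = _load_reference(config)
    curated, report = curate_cohort(
        cohort,
        ref=ref,
        outlier_alpha=config.outlier_alpha if config.outlier_screen else None,
    )
    curated = [rep for rep in curated if rep.n_records > 0]
    table = cohort_diversity_table(curated)
    cache.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(cache, sep="\t", index=False)
    report_path.write_text(report.to_json())
    return table, report.to_dict()


def run_cross_sectional(config: RunConfig) -> dict:
    """Cross-sectional analysis of whole-blood repertoires.

    Produces, for each response, general and piecewise weighted-regression
    tables for all donors and for each sex, plus the curation accounting
    and optional depth profiles.  Returns a dict of output paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    cohort = manifest.load_repertoires()
    table, report = _curated_diversity(config, cohort, out)

    outputs = {"diversity_table": str(out / "diversity.tsv")}
    table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    (out / "curation_report.json").write_text(json.dumps(report, indent=1))
    outputs["curation_report"] = str(out / "curation_report.json")

    for response in ("status_J", "sequence_J"):
        fits = cross_sectional_table(table, response, min_group=config.min_group)
        path = out / f"models_{response}.tsv"
        fits.to_csv(path, sep="\t", index=False)
        outputs[f"models_{response}"] = str(path)

    if config.depth_profile:
        ref = _load_reference(config)
        curated, _ = curate_cohort(
            cohort, ref=ref,
            outlier_alpha=config.outlier_alpha if config.outlier_screen else None,
        )
        profiles = []
        for rep in curated:
            prof = depth_profile(
                rep,
                depths=[d for d in config.depths if d <= rep.total_copies],
                n_replicates=config.n_replicates,
                seed=config.seed,
            )
            prof.table["sample_id"] = rep.sample_id
            profiles.append(prof.table)
        if profiles:
            allprof = pd.concat(profiles, ignore_index=True)
            allprof.to_csv(out / "depth_profile.tsv", sep="\t", index=False)
            outputs["depth_profile"] = str(out / "depth_profile.tsv")

    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1))
    outputs["provenance"] = str(out / "provenance.json")
    return outputs


def run_longitudinal(config: RunConfig) -> dict:
    """Longitudinal analysis of sorted CD4/CD8 repertoire pairs.

    Reconstitutes a whole-blood sample per donor-timepoint (replicated,
    averaged), fits the donor-random-intercept models on the merged
    diversities, and fits the cell-type models on the sorted compartments.
    Writes coefficient tables, group summaries and ICCs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    cohort = manifest.load_repertoires()
    ref = _load_reference(config)

    by_key: dict[tuple[str, Optional[int]], dict[str, Repertoire]] = {}
    for rep in cohort:
        if rep.compartment not in (Compartment.CD4, Compartment.CD8):
            raise ValueError(
                f"longitudinal run expects sorted CD4/CD8 samples, got "
                f"{rep.compartment} for {rep.sample_id!r}"
            )
        by_key.setdefault((rep.donor_id, rep.timepoint), {})[
            rep.compartment.value
        ] = rep
    unpaired = [k for k, v in by_key.items() if set(v) != {"CD4", "CD8"}]
    if unpaired:
        raise ValueError(f"unpaired compartments for donor-timepoints: {unpaired}")

    merged_rows = []
    sorted_rows = []
    for (donor, tp), pair in sorted(by_key.items()):
        cd4, _ = curate_records(pair["CD4"], ref)
        cd8, _ = curate_records(pair["CD8"], ref)
        cd4, cd8 = collapse_clones(cd4), collapse_clones(cd8)
        recon = reconstitute_whole_blood(
            cd4, cd8, n_replicates=config.n_replicates, seed=config.seed
        )
        base = {
            "donor": donor,
            "timepoint": tp,
            "age": cd4.age,
            "sex": cd4.sex.value if cd4.sex else None,
        }
        merged_rows.append(
            {
                **base,
                "N": recon.representative.total_copies,
                "status_J": recon.status_J,
                "sequence_J": recon.sequence_J,
            }
        )
        for name, rep in (("CD4", cd4), ("CD8", cd8)):
            sorted_rows.append(
                {
                    **base,
                    "celltype": name,
                    "N": rep.total_copies,
                    "status_J": status_diversity(rep).J,
                    "sequence_J": sequence_diversity(rep).J,
                }
            )

    merged = pd.DataFrame(merged_rows)
    sorted_tbl = pd.DataFrame(sorted_rows)
    merged.to_csv(out / "merged_diversity.tsv", sep="\t", index=False)
    sorted_tbl.to_csv(out / "sorted_diversity.tsv", sep="\t", index=False)

    outputs = {
        "merged_diversity": str(out / "merged_diversity.tsv"),
        "sorted_diversity": str(out / "sorted_diversity.tsv"),
    }
    for response in ("status_J", "sequence_J"):
        spec, fit = lrt_backward_select(merged, MixedSpec(response=response))
        _write_mixed_outputs(out, f"wholeblood_{response}", fit, outputs)
        ct_full = MixedSpec(
            response=response,
            fixed=("AGE", "SEX", "AGE:SEX", "CELLTYPE", "AGE:CELLTYPE"),
            random=(GROUP_DONOR, GROUP_DONOR_CELLTYPE),
        )
        spec_ct, fit_ct = lrt_backward_select(sorted_tbl, ct_full)
        _write_mixed_outputs(out, f"celltype_{response}", fit_ct, outputs)

    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1))
    outputs["provenance"] = str(out / "provenance.json")
    return outputs


def _write_mixed_outputs(out: Path, label: str, fit, outputs: dict) -> None:
    coefs = CoefficientTable.from_fit(fit)
    rows = []
    celltypes = [None] if not fit.donor_celltype_offsets else [None, "CD8"]
    for sex in ("male", "female"):
        try:
            for ct in celltypes:
                summ = summarize_initial_diversity(coefs, sex, ct)
                rows.append(
                    {
                        "sex": sex,
                        "cell_type": ct or "whole_blood",
                        "mean_initial": summ.mean_initial,
                        "sd_initial": summ.sd_initial,
                        "slope_per_year": slope_for_group(coefs, sex, ct),
                    }
                )
        except ValueError:
            continue
    pd.DataFrame(rows).to_csv(out / f"summary_{label}.tsv", sep="\t", index=False)
    payload = {
        "fixed_effects": fit.params,
        "donor_intercepts": fit.donor_intercepts,
        "donor_celltype_offsets": fit.donor_celltype_offsets,
        "variance_components": fit.var_components,
        "residual_variance": fit.resid_var,
        "icc": {g: icc(fit, g) for g in fit.var_components},
        "llf": fit.llf,
    }
    (out / f"mixedfit_{label}.json").write_text(json.dumps(payload, indent=1))
    outputs[f"summary_{label}"] = str(out / f"summary_{label}.tsv")
    outputs[f"mixedfit_{label}"] = str(out / f"mixedfit_{label}.json")
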