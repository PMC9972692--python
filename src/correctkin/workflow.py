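"""End-to-end pipeline: import, cohort assembly, overlap, kinship,
correction, filtering and reporting, with a reproducible run log."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .correct_filter import (
    HARD_THRESHOLD_DEFAULT,
    correct_kinship,
    filter_relatives,
    fit_error_model,
    kin_groups,
)
from .datatypes import GenotypeDataset, MarkerTable, SampleTable
from .genotype_io import read_dataset
from .haploidize import rpsh
from .kinship import estimate_kinship, read_external_kinship, write_kinship_tsv
from .overlap import filter_min_markers, overlap_matrix, write_overlap_tsv

log = logging.getLogger(__name__)

MIN_REFERENCE_ADVISORY = 50  # ~50-100 unrelated references suffice


@dataclass
class RunConfig:
    """Pipeline settings; fully serialized into the run log."""

    inputs: list = field(default_factory=list)  # (prefix, format) tuples
    reference_populations: list = field(default_factory=list)
    K: int | str = "auto"
    maf_min: float = 0.05
    min_typed: int = 100_000
    Z: float = 6.0
    hard_threshold: float | None = HARD_THRESHOLD_DEFAULT
    use_error_model: bool = True
    pseudo_haploidize: bool = False
    report_all_pairs: bool = False
    external_kinship: str | None = None
    seed: int = 0
    outdir: str = "correctkin_out"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Flat key=value config; `input` lines may repeat as prefix:format."""
        cfg = cls()
        casts = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key == "input":
                    prefix, _, fmt = value.partition(":")
                    cfg.inputs.append((prefix, fmt or "plink"))
                elif key == "reference_populations":
                    cfg.reference_populations = [
                        v.strip() for v in value.split(",") if v.strip()
                    ]
                elif key in ("maf_min", "Z"):
                    setattr(cfg, key, float(value))
                elif key == "hard_threshold":
                    setattr(cfg, key, None if value.lower() == "none" else float(value))
                elif key in ("min_typed", "seed"):
                    setattr(cfg, key, int(value))
                elif key == "K":
                    cfg.K = value if value == "auto" else int(value)
                elif key in ("use_error_model", "pseudo_haploidize", "report_all_pairs"):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif key in ("external_kinship", "outdir"):
                    setattr(cfg, key, value)
                elif key in casts:
                    setattr(cfg, key, value)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cfg

    def serialize(self) -> str:
        lines = []
        for prefix, fmt in self.inputs:
            lines.append(f"input={prefix}:{fmt}")
        lines.append(
            "reference_populations=" + ",".join(self.reference_populations)
        )
        for key in (
            "K",
            "maf_min",
            "min_typed",
            "Z",
            "hard_threshold",
            "use_error_model",
            "pseudo_haploidize",
            "report_all_pairs",
            "external_kinship",
            "seed",
            "outdir",
        ):
            lines.append(f"{key}={getattr(self, key)}")
        return "\n".join(lines) + "\n"


def merge_cohorts(ds_list) -> GenotypeDataset:
    """Sample-wise concatenation of datasets sharing one marker panel.

    Panels must agree in marker id, position and alleles; the first 10
    discordant markers are listed on mismatch.  Duplicate sample ids are
    rejected.
    """
    ds_list = [ds for ds in ds_list if ds.n_samples > 0]
    if not ds_list:
        raise ValueError("nothing to merge")
    if len(ds_list) == 1:
        return ds_list[0].copy()
    ref = ds_list[0].markers.table
    check_cols = ["marker_id", "chromosome", "position", "allele_major", "allele_minor"]
    for other in ds_list[1:]:
        ot = other.markers.table
        if len(ot) != len(ref):
            raise ValueError(
                f"marker panels differ in size: {len(ref)} vs {len(ot)}"
            )
        neq = (ref[check_cols].to_numpy(object) != ot[check_cols].to_numpy(object)).any(axis=1)
        if neq.any():
            bad = ref.loc[neq, "marker_id"].head(10).tolist()
            raise ValueError(f"marker panels disagree, first discordant markers: {bad}")
    tables = [ds.samples.table for ds in ds_list]
    all_ids = pd.concat(tables)["sample_id"]
    if all_ids.duplicated().any():
        dup = all_ids[all_ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id across cohorts: {dup!r}")
    samples = SampleTable(pd.concat(tables, ignore_index=True))
    calls = np.vstack([ds.calls for ds in ds_list])
    mode = (
        "pseudo_haploid"
        if all(ds.ploidy_mode == "pseudo_haploid" for ds in ds_list)
        else "diploid"
    )
    return GenotypeDataset(ds_list[0].markers, samples, calls, mode)


def run_pipeline(cfg: RunConfig, dataset: GenotypeDataset | None = None) -> dict:
    """Execute the full workflow and write all intermediate artifacts.

    ``dataset`` may be supplied directly (tests, library use); otherwise the
    configured input filesets are read and merged.  Samples whose population
    label is in ``cfg.reference_populations`` are treated as reference; by
    default only pairs involving at least one test sample are reported
    (``report_all_pairs`` reproduces an all-vs-all screen).
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    log_lines = ["# correctkin run log", cfg.serialize()]

    def stage(msg):
        log.info(msg)
        log_lines.append(msg)

    if dataset is None:
        parts = [read_dataset(prefix, fmt) for prefix, fmt in cfg.inputs]
        ds = merge_cohorts(parts)
    else:
        ds = dataset
    stage(f"input: {ds.n_samples} samples x {ds.n_markers} markers ({ds.ploidy_mode})")

    ds = ds.restrict_autosomes()
    stage(f"autosome restriction: {ds.n_markers} markers retained")

    if cfg.reference_populations:
        roles = [
            "reference" if p in cfg.reference_populations else "test"
            for p in ds.samples.table["population_label"]
        ]
        ds.samples.table["role"] = roles
    n_ref = int((ds.samples.table["role"] == "reference").sum())
    if 0 < n_ref < MIN_REFERENCE_ADVISORY:
        stage(
            f"warning: only {n_ref} reference samples; ~50-100 unrelated "
            "references are recommended"
        )

    ds, report = filter_min_markers(ds, cfg.min_typed)
    removed = report[report["removed"]]
    stage(f"min-marker filter ({cfg.min_typed}): removed {len(removed)} samples")
    report.to_csv(os.path.join(cfg.outdir, "typed_counts.tsv"), sep="\t", index=False)

    if cfg.pseudo_haploidize and ds.ploidy_mode == "diploid":
        ds = rpsh(ds, cfg.seed)
        stage(f"random pseudo-haploidization with seed {cfg.seed}")

    om = overlap_matrix(ds)
    write_overlap_tsv(
        om,
        os.path.join(cfg.outdir, "overlap_fraction.tsv"),
        os.path.join(cfg.outdir, "overlap_counts.tsv"),
    )
    stage(f"overlap matrix over panel of {om.panel_size} markers")

    if cfg.external_kinship:
        kin = read_external_kinship(cfg.external_kinship, ds.sample_ids)
        stage(f"external kinship matrix loaded from {cfg.external_kinship}")
    else:
        kin = estimate_kinship(ds, K=cfg.K, maf_min=cfg.maf_min)
        stage(
            f"kinship estimated with K={kin.settings['K']}, "
            f"{kin.settings['n_markers_kept']} markers kept at maf>={cfg.maf_min}"
        )
    write_kinship_tsv(kin, os.path.join(cfg.outdir, "kinship_raw.tsv"))

    corrected = correct_kinship(kin.phi, om.fraction)
    pd.DataFrame(corrected, index=ds.sample_ids, columns=ds.sample_ids).to_csv(
        os.path.join(cfg.outdir, "kinship_corrected.tsv"), sep="\t", float_format="%.10g"
    )

    model = None
    if cfg.use_error_model:
        try:
            model = fit_error_model(corrected, om.counts, Z=cfg.Z)
            stage(
                f"error model fitted on {model.diagnostics['n_pairs_used']} pairs "
                f"(sd = {model.a:.3g} + {model.b:.3g}/sqrt(n))"
            )
        except ValueError as exc:
            if cfg.hard_threshold is None:
                raise
            stage(f"error model unavailable ({exc}); hard threshold only")
    calls = filter_relatives(
        kin.phi, corrected, om, model=model, hard_threshold=cfg.hard_threshold
    )

    if not cfg.report_all_pairs:
        role = dict(zip(ds.sample_ids, ds.samples.table["role"]))
        keep = [
            role.get(a) == "test" or role.get(b) == "test"
            for a, b in zip(calls["sample1"], calls["sample2"])
        ]
        calls = calls[keep].reset_index(drop=True)
    calls = kin_groups(calls)
    out_path = os.path.join(cfg.outdir, "relatives.tsv")
    calls.to_csv(out_path, sep="\t", index=False, float_format="%.6f")
    stage(f"{len(calls)} relative pairs reported -> {out_path}")

    try:
        from .plots import plot_corrected_vs_overlap

        plot_corrected_vs_overlap(
            corrected, om, model, os.path.join(cfg.outdir, "corrected_vs_overlap.png")
        )
    except ImportError:  # matplotlib is optional
        pass

    with open(os.path.join(cfg.outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return {
        "dataset": ds,
        "overlap": om,
        "kinship": kin,
        "corrected": corrected,
        "error_model": model,
        "relatives": calls,
    }
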