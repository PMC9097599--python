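"""End-to-end orchestration: configured runs, reports, reproducibility
metadata.

Two entry points: :func:`run_instability` chains the per-sample shallow-WGS
stages (bin counts → GC correction → stable regions → normalization →
segmentation → smoothing → LST/GIN) and :func:`run_cohort_report` assembles
cohort-level outputs (clinical summary, driver-detection cross-tab, paired
fragment comparison, variant partition, survival split). Every run writes a
manifest listing inputs and outputs with checksums and the full parameter
set, so results are attributable and repeatable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import cross_tab_status, parse_clinical_table, summarize_cohort
from .coverage import (
    BinnedCoverageProfile,
    HetSNPTable,
    StableRegionParams,
    bin_fragments,
    correct_gc,
    identify_stable_regions,
    normalize_and_ratio,
)
from .fragments import compare_paired
from .instability import ScoreParams, score_sample
from .layout import GenomeLayout
from .survival import (
    HIGH_GROUP,
    LOW_GROUP,
    dichotomize_by_median,
    km_estimate,
    log_rank,
    survival_rate_at,
)
from .variants import (
    SampleVariantSet,
    detect_driver,
    filter_calls,
    load_panel,
    partition_alterations,
    read_calls_tsv,
    restrict_to_panel,
)

logger = logging.getLogger("csflm")


@dataclass
class RunConfig:
    """All inputs and tunables of a pipeline run.

    Defaults reproduce the published analysis constants: 1-Mb bins, 3-Mb
    smoothing, 10-Mb LST flanks, 0.1% VAF and 4-read variant filters,
    150-bp short-fragment bound, 6-month survival horizon.
    """

    # inputs
    sample: str | None = None
    germline: str | None = None
    snps: str | None = None
    layout: str | None = None
    clinical_table: str | None = None
    scores_json: str | None = None
    paired_values: str | None = None
    variants_csf: str | None = None
    variants_plasma: str | None = None
    panel: str | None = None
    # tunables
    bin_size: int = 1_000_000
    stable: StableRegionParams = field(default_factory=StableRegionParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    min_vaf: float = 0.001
    min_reads: int = 4
    horizon: float = 6.0
    seed: int = 0
    outdir: str = "csflm_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if isinstance(data.get("stable"), dict):
            data["stable"] = StableRegionParams(**data["stable"])
        if isinstance(data.get("score"), dict):
            data["score"] = ScoreParams(**data["score"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig) -> None:
        self.outdir = outdir
        self.data = {
            "package": "csflm",
            "version": __version__,
            "parameters": config.to_dict(),
            "inputs": {},
            "outputs": {},
            "gaps": [],
            "timings": {},
        }

    def add_input(self, name: str, path) -> None:
        if path is not None and Path(path).exists():
            self.data["inputs"][name] = {
                "path": str(path), "sha256": _sha256(Path(path)),
            }

    def add_output(self, path: Path) -> None:
        self.data["outputs"][path.name] = {"sha256": _sha256(path)}

    def add_gap(self, message: str) -> None:
        self.data["gaps"].append(message)

    def time_stage(self, stage: str, started: float) -> None:
        self.data["timings"][stage] = round(time.perf_counter() - started, 4)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as handle:
            json.dump(self.data, handle, indent=2, sort_keys=True)
        return path


def _load_profile(path: str, layout: GenomeLayout, sample_id: str) -> BinnedCoverageProfile:
    if str(path).endswith((".bam", ".sam", ".cram")):
        return bin_fragments(path, layout, sample_id=sample_id)
    return BinnedCoverageProfile.from_tsv(path, layout=layout, sample_id=sample_id)


def run_instability(config: RunConfig) -> dict:
    """Score one sample/germline pair; write scores, SEG, BED, manifest.

    Deterministic for a fixed config (the segmentation permutation RNG is
    seeded from ``config.seed`` unless the score params carry their own).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    for name in ("sample", "germline", "snps", "layout"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"instability stage: required input {name!r} missing at {path}"
            )
        manifest.add_input(name, path)

    started = time.perf_counter()
    layout = GenomeLayout.from_tsv(config.layout, bin_size=config.bin_size)
    sample = _load_profile(config.sample, layout, "sample")
    germline = _load_profile(config.germline, layout, "germline")
    snps = HetSNPTable.from_tsv(config.snps)
    manifest.time_stage("load", started)

    started = time.perf_counter()
    sample = correct_gc(sample)
    germline = correct_gc(germline)
    stable = identify_stable_regions(germline, snps, config.stable)
    profile = normalize_and_ratio(sample, germline, stable)
    manifest.time_stage("normalize", started)

    started = time.perf_counter()
    params = config.score
    if params.seed is None:
        params = dataclasses.replace(params, seed=config.seed)
    scores, smoothed = score_sample(profile, stable, params)
    manifest.time_stage("score", started)

    scores_path = outdir / "scores.json"
    with open(scores_path, "w") as handle:
        json.dump(scores.to_dict(), handle, indent=2, sort_keys=True)
    seg_path = outdir / "segments.seg"
    smoothed.to_seg(seg_path)
    bed_path = outdir / "stable_regions.bed"
    stable.to_bed(bed_path)
    for path in (scores_path, seg_path, bed_path):
        manifest.add_output(path)
    manifest.write()
    logger.info("instability scores written to %s", outdir)
    return scores.to_dict()


def _variant_sets_by_patient(path: str, compartment: str, panel: set[str],
                             min_vaf: float, min_reads: int) -> dict[str, SampleVariantSet]:
    calls = restrict_to_panel(
        filter_calls(read_calls_tsv(path), min_vaf=min_vaf, min_reads=min_reads),
        panel,
    )
    by_patient: dict[str, list] = {}
    for call in calls:
        by_patient.setdefault(call.sample_id.split("-")[0], []).append(call)
    return {
        pid: SampleVariantSet.from_calls(compartment, pid, patient_calls)
        for pid, patient_calls in by_patient.items()
    }


def run_cohort_report(config: RunConfig) -> dict:
    """Assemble cohort-level outputs into ``config.outdir``.

    Sections with missing inputs are skipped and listed under "gaps" in the
    manifest rather than aborting the whole report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    written: list[Path] = []

    records = parse_clinical_table(config.clinical_table)
    manifest.add_input("clinical_table", config.clinical_table)
    summary = summarize_cohort(records)
    path = outdir / "cohort_summary.json"
    with open(path, "w") as handle:
        json.dump(summary.to_dict(), handle, indent=2, sort_keys=True)
    written.append(path)

    # --- variant partition + driver detection ---------------------------
    if config.variants_csf and config.variants_plasma:
        manifest.add_input("variants_csf", config.variants_csf)
        manifest.add_input("variants_plasma", config.variants_plasma)
        panel = load_panel(config.panel)
        csf_sets = _variant_sets_by_patient(
            config.variants_csf, "CSF", panel, config.min_vaf, config.min_reads
        )
        plasma_sets = _variant_sets_by_patient(
            config.variants_plasma, "plasma", panel, config.min_vaf, config.min_reads
        )
        per_patient = []
        totals = np.zeros(3, dtype=int)
        for pid in sorted(set(csf_sets) | set(plasma_sets)):
            csf = csf_sets.get(pid) or SampleVariantSet("CSF", pid)
            plasma = plasma_sets.get(pid) or SampleVariantSet("plasma", pid)
            result = partition_alterations(csf, plasma)
            per_patient.append(result.to_dict())
            totals += np.array(result.counts)
        partition = {
            "per_patient": per_patient,
            "pooled": {
                "shared": int(totals[0]),
                "csf_only": int(totals[1]),
                "plasma_only": int(totals[2]),
                "total": int(totals.sum()),
            },
        }
        path = outdir / "partition_counts.json"
        with open(path, "w") as handle:
            json.dump(partition, handle, indent=2, sort_keys=True)
        written.append(path)

        by_id = {r.patient_id: r for r in records}
        detection_rows = []
        plasma_detected: dict[str, bool] = {}
        for pid, record in by_id.items():
            row = {"patient_id": pid, "driver": record.driver_alteration}
            for label, sets in (("csf", csf_sets), ("plasma", plasma_sets)):
                variant_set = sets.get(pid)
                if variant_set is None:
                    detected, vaf = False, None
                else:
                    detected, vaf = detect_driver(
                        variant_set, record.driver_alteration
                    )
                row[f"detected_{label}"] = detected
                row[f"vaf_{label}"] = vaf
            detection_rows.append(row)
            plasma_detected[pid] = bool(row["detected_plasma"])
        detection = pd.DataFrame(detection_rows)
        path = outdir / "driver_detection.tsv"
        detection.to_csv(path, sep="\t", index=False)
        written.append(path)
        path = outdir / "detection_by_status.tsv"
        cross_tab_status(records, plasma_detected).to_csv(path, sep="\t")
        written.append(path)
    else:
        manifest.add_gap("variant tables missing: partition and detection skipped")

    # --- paired fragment comparison -------------------------------------
    if config.paired_values and Path(config.paired_values).exists():
        manifest.add_input("paired_values", config.paired_values)
        pairs = pd.read_csv(config.paired_values, sep="\t")
        statistic, p = compare_paired(pairs["csf"], pairs["plasma"])
        path = outdir / "fragment_comparison.json"
        with open(path, "w") as handle:
            json.dump(
                {
                    "n_pairs": int(len(pairs)),
                    "wilcoxon_statistic": statistic,
                    "p_value": p,
                    "median_csf": float(pairs["csf"].median()),
                    "median_plasma": float(pairs["plasma"].median()),
                },
                handle, indent=2, sort_keys=True,
            )
        written.append(path)
    else:
        manifest.add_gap("paired fragment values missing: comparison skipped")

    # --- survival split --------------------------------------------------
    if config.scores_json and Path(config.scores_json).exists():
        manifest.add_input("scores_json", config.scores_json)
        with open(config.scores_json) as handle:
            lst_by_patient = {
                k: float(v) for k, v in json.load(handle).items()
            }
        survivors = [
            r.to_survival() for r in records if r.patient_id in lst_by_patient
        ]
        if len(survivors) < 2:
            warnings.warn("fewer than 2 scored patients; survival section skipped")
            manifest.add_gap("fewer than 2 scored patients: survival skipped")
        else:
            groups = dichotomize_by_median(
                {r.patient_id: lst_by_patient[r.patient_id] for r in survivors}
            )
            for record in survivors:
                record.group = groups[record.patient_id]
            high = [r for r in survivors if r.group == HIGH_GROUP]
            low = [r for r in survivors if r.group == LOW_GROUP]
            result: dict = {
                "cutoff": float(np.median(list(lst_by_patient.values()))),
                "n_high": len(high),
                "n_low": len(low),
            }
            curves = {}
            for label, group_records in (("high", high), ("low", low)):
                if not group_records:
                    continue
                curve = km_estimate(group_records)
                curves[label] = curve
                result[f"median_os_{label}"] = curve.median
                result[f"survival_at_{config.horizon:g}m_{label}"] = (
                    survival_rate_at(curve, config.horizon)
                )
            if high and low:
                chi2, p = log_rank(high, low)
                result["logrank_chi2"] = chi2
                result["logrank_p"] = p
            path = outdir / "km_results.json"
            with open(path, "w") as handle:
                json.dump(result, handle, indent=2, sort_keys=True)
            written.append(path)
            for label, curve in curves.items():
                path = outdir / f"km_curve_{label}.tsv"
                curve.to_frame().to_csv(path, sep="\t", index=False)
                written.append(path)
    else:
        manifest.add_gap("per-patient scores missing: survival section skipped")

    for path in written:
        manifest.add_output(path)
    manifest_path = manifest.write()
    logger.info("cohort report written to %s", outdir)
    return {"outputs": [p.name for p in written], "manifest": str(manifest_path),
            "gaps": manifest.data["gaps"]}
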