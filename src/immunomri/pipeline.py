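"""End-to-end study orchestration: simulate/load -> kinetics -> ADC -> TME -> associations.

The pipeline reproduces the shape of a window-of-opportunity analysis: each
patient contributes paired pre/post MRI feature sets, dual-read TIL deciles
and expression samples; outputs are a Spearman feature-vs-TIL grid, paired
t-tests, signature scores with group tests, a two-group clustering and a
report with full provenance (package version, config hash, seed).

Patients with missing pieces degrade gracefully: TIL-non-evaluable patients
drop out of the correlation table via pairwise deletion, and a dichotomy
group too small to test is skipped with a log entry rather than aborting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import fit_adc_map, mean_adc, DwiSeries
from .assoc import build_correlation_table, cohort_summary, dichotomize, paired_ttest
from .cohort import Cohort, CohortSpec, make_cohort
from .datasets import default_shift_constants
from .dce import DceSeries, summarize_dce
from .io import read_bvals, read_mask, read_table, read_volume, write_table
from .tme import differential_signature_test, hierarchical_cluster, normalize_expression, score_signatures

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_pipeline", "process_patient_images"]


@dataclass
class StudyConfig:
    """Inputs and thresholds for one study run.

    Either ``simulate`` is true (a cohort is generated from ``cohort``) or
    the three table paths must point at existing files. Imaging thresholds
    default to the standard breast-DCE values.
    """

    simulate: bool = True
    cohort: CohortSpec = field(default_factory=CohortSpec)
    features_csv: str | None = None
    tils_csv: str | None = None
    expression_tsv: str | None = None
    housekeepers: list[str] = field(default_factory=list)
    pe_threshold: float = 50.0
    ser_threshold: float = 1.1
    delta_pe_cut: float = -10.0
    adc_cut: float = 0.92e-3
    dichotomy_strategy: str = "fixed"
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.simulate:
            self.cohort.validate()
            return
        missing = [name for name, p in
                   (("features_csv", self.features_csv), ("tils_csv", self.tils_csv))
                   if p is None or not Path(p).exists()]
        if missing:
            raise ValueError(f"config invalid; missing or nonexistent inputs: {missing}")
        if self.pe_threshold <= 0 or self.ser_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def digest(self) -> str:
        d = asdict(self)
        d.pop("output_dir", None)  # where the report lands is not part of its identity
        d["cohort"]["target_correlations"] = sorted(
            (list(k), v) for k, v in self.cohort.target_correlations.items()
        )
        if d["cohort"]["signature_defs"] is not None:
            d["cohort"]["signature_defs"] = {
                k: list(v) for k, v in d["cohort"]["signature_defs"].items()
            }
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    features: pd.DataFrame
    til_summary: pd.DataFrame
    correlation_table: pd.DataFrame
    til_paired_test: dict
    dichotomies: pd.DataFrame
    signature_scores: pd.DataFrame | None
    signature_tests: dict[str, pd.DataFrame]
    cluster_labels: pd.Series | None
    cluster_order: list[str] | None
    summary: dict
    provenance: dict


def process_patient_images(
    pre_dce: DceSeries, post_dce: DceSeries, dce_roi: np.ndarray,
    pre_dwi: DwiSeries, post_dwi: DwiSeries, dwi_roi: np.ndarray,
    pe_threshold: float = 50.0, ser_threshold: float = 1.1,
) -> dict[str, float]:
    """Full image-derived feature row for one patient (both timepoints)."""
    row: dict[str, float] = {}
    for tp, dce_series, dwi_series in (("pre", pre_dce, pre_dwi), ("post", post_dce, post_dwi)):
        ks = summarize_dce(dce_series, dce_roi, pe_threshold=pe_threshold,
                           ser_threshold=ser_threshold, timepoint_label=tp)
        row[f"{tp}_ftv"] = ks.ftv
        row[f"{tp}_wf"] = ks.wf
        row[f"{tp}_pe"] = ks.peak_pe
        row[f"{tp}_ser"] = ks.peak_ser
        row[f"{tp}_adc"] = mean_adc(fit_adc_map(dwi_series, dwi_roi), dwi_roi)
    return row


def load_patient_images(entry: dict, pe_threshold: float, ser_threshold: float) -> dict[str, float]:
    """Feature row from a per-patient file manifest (NIfTI paths + b-value sidecar)."""
    def dce(tp):
        s0, zooms = read_volume(entry[f"{tp}_s0"])
        s1, _ = read_volume(entry[f"{tp}_s1"])
        s2, _ = read_volume(entry[f"{tp}_s2"])
        return DceSeries(s0=s0, s1=s1, s2=s2, voxel_size=zooms)

    def dwi(tp):
        paths = entry[f"{tp}_dwi"]
        vols, zooms = [], None
        for p in paths:
            v, zooms = read_volume(p)
            vols.append(v)
        bvals = read_bvals(entry["bvals"], n_expected=len(paths))
        return DwiSeries(volumes=vols, b_values=bvals, voxel_size=zooms)

    pre_dce, post_dce = dce("pre"), dce("post")
    roi = read_mask(entry["dce_roi"], expect_shape=pre_dce.s0.shape)
    pre_dwi, post_dwi = dwi("pre"), dwi("post")
    dwi_roi = read_mask(entry["dwi_roi"], expect_shape=pre_dwi.volumes[0].shape)
    return process_patient_images(pre_dce, post_dce, roi, pre_dwi, post_dwi, dwi_roi,
                                  pe_threshold, ser_threshold)


def _til_summary_from_long(tils_long: pd.DataFrame) -> pd.DataFrame:
    from .tme import build_til_records
    rows = {}
    for rec in build_til_records(tils_long):
        rows[rec.patient] = {"pre_til": rec.pre_combined, "post_til": rec.post_combined,
                             "delta_til": rec.delta_til}
    return pd.DataFrame(rows).T.astype(float)


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Execute all stages in dependency order; deterministic given the config."""
    config.validate()

    cohort: Cohort | None = None
    if config.simulate:
        log.info("stage simulate: generating cohort of %d patients (seed %d)",
                 config.cohort.n_patients, config.cohort.seed)
        cohort = make_cohort(config.cohort)
        features = cohort.features
        til_summary = cohort.til_summary()
        expression = cohort.expression
        housekeepers = cohort.housekeepers
        gene_sets = cohort.gene_sets
        annotations = cohort.sample_annotations
    else:
        log.info("stage load: reading cohort tables")
        features = read_table(config.features_csv).set_index("patient")
        til_summary = _til_summary_from_long(read_table(config.tils_csv))
        expression = (pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
                      if config.expression_tsv else None)
        housekeepers = config.housekeepers
        gene_sets = CohortSpec().gene_sets()
        annotations = None

    # --- associations ---
    log.info("stage associate: correlation grid and paired tests")
    corr = build_correlation_table(features, til_summary)
    paired = til_summary.dropna()
    til_test = {}
    if len(paired) >= 2:
        res = paired_ttest(paired["pre_til"], paired["post_til"])
        til_test = {"t": res.t, "p": res.p, "mean_diff": res.mean_diff,
                    "n": res.n, "degenerate": res.degenerate}

    delta_pe = features["post_pe"] - features["pre_pe"]
    labels = dichotomize(delta_pe, features["pre_adc"], strategy=config.dichotomy_strategy,
                         delta_pe_cut=config.delta_pe_cut, adc_cut=config.adc_cut)
    dich = pd.concat([labels.delta_pe_class, labels.adc_class], axis=1)

    # --- TME expression analyses ---
    scores = None
    tests: dict[str, pd.DataFrame] = {}
    cluster_labels = None
    cluster_order = None
    if expression is not None and housekeepers:
        log.info("stage tme: normalization, scoring, tests, clustering")
        normalized = normalize_expression(expression, housekeepers)
        scores = score_signatures(normalized, gene_sets, default_shift_constants())
        patient_of = (annotations["patient"] if annotations is not None
                      else pd.Series({s: s.rsplit("_", 1)[0] for s in scores.columns}))
        for axis, lab in (("delta_pe_class", labels.delta_pe_class),
                          ("adc_class", labels.adc_class)):
            grp = patient_of.map(lab)
            ok = grp.notna()
            if ok.sum() < 4 or grp[ok].nunique() != 2 or grp[ok].value_counts().min() < 2:
                log.warning("skipping %s differential test: group too small", axis)
                continue
            tests[axis] = differential_signature_test(scores.loc[:, ok.to_numpy()],
                                                      grp[ok].to_numpy())
        try:
            ann = annotations.copy() if annotations is not None else pd.DataFrame(
                index=scores.columns)
            ann["delta_pe_class"] = patient_of.map(labels.delta_pe_class)
            ann["adc_class"] = patient_of.map(labels.adc_class)
            cl = hierarchical_cluster(scores, annotations=ann)
            cluster_labels, cluster_order = cl.labels, cl.order
        except ValueError as exc:
            log.warning("clustering skipped: %s", exc)

    summary = cohort_summary(features)
    provenance = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "cohort_seed": config.cohort.seed if config.simulate else None,
    }
    report = StudyReport(
        features=features, til_summary=til_summary, correlation_table=corr,
        til_paired_test=til_test, dichotomies=dich, signature_scores=scores,
        signature_tests=tests, cluster_labels=cluster_labels,
        cluster_order=cluster_order, summary=summary, provenance=provenance,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(report.features, outdir / "features.csv")
    write_table(report.til_summary, outdir / "til_summary.csv")
    write_table(report.correlation_table, outdir / "correlation_table.csv")
    write_table(report.dichotomies, outdir / "dichotomy_labels.csv")
    if report.signature_scores is not None:
        write_table(report.signature_scores, outdir / "signature_scores.csv")
        if report.cluster_order is not None:
            ordered = report.signature_scores[report.cluster_order]
            ordered.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", float_format="%.10g")
    for axis, frame in report.signature_tests.items():
        write_table(frame, outdir / f"signature_tests_{axis}.csv")
    if report.cluster_labels is not None:
        write_table(report.cluster_labels.to_frame(), outdir / "cluster_labels.csv")
    blob = {
        "provenance": report.provenance,
        "cohort_summary": report.summary,
        "til_paired_test": report.til_paired_test,
    }
    (outdir / "report.json").write_text(json.dumps(blob, indent=2, sort_keys=True))
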