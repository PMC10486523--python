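"""Tumor-microenvironment quantification.

Two independent data streams are handled here:

* Stromal tumor-infiltrating lymphocytes (TILs), scored by two pathologists
  into deciles (integer bins 0-9 standing for 0-9%, 10-19%, ..., 90-100%).
  The two reads are averaged; an immune responder is a patient whose combined
  decile rises by more than one between pre- and post-treatment tissue.

* Immune gene-signature scores from an expression panel: genes are normalized
  per sample to the geometric mean of housekeeping genes, log2-transformed,
  averaged within signature gene sets (plus an optional range-alignment
  constant), tested for group differences with a two-group fixed-effect
  linear model (pooled-variance t-test), and adjusted across signatures with
  the Benjamini-Yekutieli FDR, which is valid under arbitrary dependence.
  Samples are clustered hierarchically on z-scored scores and cut into two
  groups, immune-activated vs immune-quiescent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "TilRecord",
    "ClusterResult",
    "combine_til_reads",
    "classify_immune_response",
    "build_til_records",
    "normalize_expression",
    "qc_filter_samples",
    "score_signatures",
    "differential_signature_test",
    "hierarchical_cluster",
    "pair_cocluster_fraction",
]

RESPONDER_DELTA = 1.0  # responder iff combined decile rises by MORE than this
DISCORDANCE_DECILES = 2  # |read1 - read2| at/above this logs a warning


@dataclass
class TilRecord:
    """Dual pathologist TIL reads for one patient across the two timepoints."""

    patient: str
    pre_read1: int | None = None
    pre_read2: int | None = None
    post_read1: int | None = None
    post_read2: int | None = None
    pre_combined: float | None = None
    post_combined: float | None = None
    delta_til: float | None = None
    responder: bool | None = None  # None when non-evaluable

    @property
    def evaluable(self) -> bool:
        return self.responder is not None


def combine_til_reads(read1: int, read2: int) -> float:
    """Average the two pathologists' decile reads (half-integers preserved)."""
    for r in (read1, read2):
        if not (0 <= r <= 9) or int(r) != r:
            raise ValueError(f"TIL decile read must be an integer in 0-9, got {r!r}")
    if abs(read1 - read2) >= DISCORDANCE_DECILES:
        log.warning("discordant TIL reads: %s vs %s (>= %d deciles apart)",
                    read1, read2, DISCORDANCE_DECILES)
    return (read1 + read2) / 2.0


def classify_immune_response(
    pre_combined: float, post_combined: float, threshold: float = RESPONDER_DELTA
) -> tuple[bool, float]:
    """Responder flag and decile change (post - pre).

    A responder shows an increase of *more than* ``threshold`` deciles; an
    increase of exactly one decile is a non-responder.
    """
    delta = post_combined - pre_combined
    return delta > threshold, delta


def build_til_records(reads: pd.DataFrame) -> list[TilRecord]:
    """Assemble records from a long table (patient, timepoint, reader, decile).

    ``timepoint`` is 'pre' or 'post', ``reader`` 1 or 2. Patients missing a
    timepoint are kept but flagged non-evaluable (responder None) and logged.
    """
    records: list[TilRecord] = []
    for patient, grp in reads.groupby("patient", sort=True):
        rec = TilRecord(patient=str(patient))
        for tp in ("pre", "post"):
            sub = grp[grp["timepoint"] == tp]
            if len(sub) == 0:
                continue
            r1 = sub.loc[sub["reader"] == 1, "decile"]
            r2 = sub.loc[sub["reader"] == 2, "decile"]
            if len(r1) != 1 or len(r2) != 1:
                raise ValueError(f"patient {patient} {tp}: expected one read per reader")
            setattr(rec, f"{tp}_read1", int(r1.iloc[0]))
            setattr(rec, f"{tp}_read2", int(r2.iloc[0]))
            setattr(rec, f"{tp}_combined", combine_til_reads(int(r1.iloc[0]), int(r2.iloc[0])))
        if rec.pre_combined is not None and rec.post_combined is not None:
            rec.responder, rec.delta_til = classify_immune_response(
                rec.pre_combined, rec.post_combined
            )
        else:
            log.info("patient %s non-evaluable for TIL response (missing timepoint)", patient)
        records.append(rec)
    return records


def qc_filter_samples(
    matrix: pd.DataFrame,
    housekeepers: Sequence[str],
    blacklist: Sequence[str] = (),
    min_housekeeper_log2: float = 4.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop failed samples: explicit blacklist plus a housekeeper-signal floor.

    Vendor QC metrics are pipeline-specific, so exclusion here is explicit
    and reproducible: a sample fails when listed in ``blacklist`` or when
    the mean log2 housekeeping signal falls below ``min_housekeeper_log2``.
    Returns the filtered matrix and the excluded sample names (logged).
    """
    hk = matrix.loc[[g for g in housekeepers if g in matrix.index]]
    with np.errstate(divide="ignore"):
        hk_level = np.log2(hk.where(hk > 0)).mean(axis=0)
    excluded = sorted(set(blacklist) & set(matrix.columns)
                      | set(hk_level.index[hk_level.fillna(-np.inf) < min_housekeeper_log2]))
    if excluded:
        log.warning("qc_filter_samples: excluding %d sample(s): %s", len(excluded), excluded)
    return matrix.drop(columns=excluded), excluded


def normalize_expression(
    matrix: pd.DataFrame,
    housekeepers: Sequence[str],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Housekeeper-ratio normalization followed by log2.

    Each gene value is divided by the geometric mean of the housekeeping
    genes in the same sample, then log2-transformed. Zeros among non-
    housekeeping genes receive a pseudocount (default: half the smallest
    positive value in the matrix). ``matrix`` is genes x samples.
    """
    hk = [g for g in housekeepers if g in matrix.index]
    missing = set(housekeepers) - set(hk)
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {sorted(missing)}")
    hk_vals = matrix.loc[hk]
    bad = hk_vals <= 0
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"housekeeping gene {gene!r} has nonpositive value in sample {sample!r}"
        )
    geo = np.exp(np.log(hk_vals).mean(axis=0))  # per sample

    values = matrix.to_numpy(float)
    if (values <= 0).any():
        if pseudocount is None:
            pseudocount = float(values[values > 0].min()) / 2.0
        log.info("normalize_expression: applying pseudocount %.4g to nonpositive values",
                 pseudocount)
        values = values + pseudocount
    return pd.DataFrame(
        np.log2(values / geo.to_numpy()), index=matrix.index, columns=matrix.columns
    )


def score_signatures(
    normalized: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    shift_constants: Mapping[str, float] | float = 0.0,
) -> pd.DataFrame:
    """Signature score = mean of member-gene normalized values + constant.

    Genes missing from the matrix are dropped with a warning; an empty
    intersection is an error. Returns signatures x samples.
    """
    rows = {}
    for name, genes in gene_sets.items():
        if len(genes) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in genes if g in normalized.index]
        if not present:
            raise ValueError(f"no genes of set {name!r} present in the matrix")
        if len(present) < len(genes):
            log.warning("signature %s: %d/%d genes missing; scoring over intersection",
                        name, len(genes) - len(present), len(genes))
        const = shift_constants if np.isscalar(shift_constants) else shift_constants.get(name, 0.0)
        rows[name] = normalized.loc[present].mean(axis=0) + float(const)
    return pd.DataFrame(rows).T


def differential_signature_test(
    scores: pd.DataFrame, group_labels: Sequence
) -> pd.DataFrame:
    """Two-group fixed-effect linear model per signature, BY-adjusted.

    Fitting score = mu + group + error with a single binary factor is
    equivalent to a pooled-variance two-sample t-test, which is what is
    computed. P-values are adjusted across all signatures with the
    Benjamini-Yekutieli step-up procedure. Returns a frame indexed by
    signature with columns group_diff, t, p_raw, p_by; ``group_diff`` is the
    mean of the second sorted group level minus the first.
    """
    labels = pd.Series(list(group_labels), index=scores.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = scores.loc[:, labels == levels[0]].to_numpy(float)
    b = scores.loc[:, labels == levels[1]].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=True)
    diff = b.mean(axis=1) - a.mean(axis=1)
    degenerate = np.isnan(t)  # zero variance in both groups and equal means
    if degenerate.any():
        log.warning("differential_signature_test: %d degenerate signature(s), p set to 1",
                    int(degenerate.sum()))
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    p_by = multipletests(p, method="fdr_by")[1]
    return pd.DataFrame(
        {"group_diff": diff, "t": t, "p_raw": p, "p_by": p_by}, index=scores.index
    )


@dataclass
class ClusterResult:
    """Two-group hierarchical clustering of samples on signature scores."""

    linkage: np.ndarray
    order: list[str]  # sample ids in dendrogram leaf order
    labels: pd.Series  # sample -> 'immune-activated' | 'immune-quiescent'
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)


def hierarchical_cluster(
    scores: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Cluster samples on z-scored signature scores and cut into two groups.

    Signatures are z-scored across samples (constant signatures dropped);
    Euclidean distance with average linkage by default. The group whose mean
    raw score is higher is labeled immune-activated.
    """
    if scores.shape[1] < 3:
        raise ValueError("need at least three samples to cluster")
    sd = scores.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("score matrix is constant; no structure to cluster")
    z = scores.loc[keep].sub(scores.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)

    Z = hierarchy.linkage(z.T.to_numpy(), method=method, metric=metric)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    order_idx = hierarchy.leaves_list(Z)
    samples = list(scores.columns)

    means = {g: scores.loc[:, cut == g].mean().mean() for g in np.unique(cut)}
    activated_group = max(means, key=means.get)
    labels = pd.Series(
        ["immune-activated" if c == activated_group else "immune-quiescent" for c in cut],
        index=samples,
        name="cluster",
    )
    ann = annotations.copy() if annotations is not None else pd.DataFrame(index=samples)
    return ClusterResult(
        linkage=Z, order=[samples[i] for i in order_idx], labels=labels, annotations=ann
    )


def pair_cocluster_fraction(result: ClusterResult, patient_of_sample: Mapping[str, str]) -> float:
    """Fraction of patients whose pre/post samples sit side by side.

    "Clustered together" is read the way a heatmap shows it: the patient's
    two samples occupy adjacent leaves of the dendrogram. Patients without
    exactly two samples are ignored.
    """
    pos = {s: i for i, s in enumerate(result.order)}
    by_patient: dict[str, list[int]] = {}
    for s in result.labels.index:
        by_patient.setdefault(str(patient_of_sample[s]), []).append(pos[s])
    pairs = [v for v in by_patient.values() if len(v) == 2]
    if not pairs:
        raise ValueError("no patient with exactly two samples")
    hits = sum(abs(a - b) == 1 for a, b in pairs)
    return hits / len(pairs)
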