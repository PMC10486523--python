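"""Synthetic patient cohort with a controlled imaging-immune correlation structure.

A Gaussian copula generates per-patient MRI features (FTV, WF, peak SER,
peak PE, mean ADC, at both timepoints) jointly with latent TIL quantities so
that requested Spearman correlations are realized: targets are mapped to
latent Pearson correlations via r = 2 sin(pi * rho / 6) and every marginal
transform downstream is monotone, which leaves Spearman invariant.

Because the headline targets (e.g. change-in-PE vs change-in-TILs -0.69,
pre-ADC vs change-in-TILs -0.67, plus positive WF/PE targets) are mutually
infeasible when all other correlations are forced to zero, feature-feature
correlations among variables loading on the same TIL quantity are completed
with a one-factor model (corr(F_i, F_j) = r_i * r_j), which is positive
semi-definite by construction; explicit targets always win and the final
matrix is still checked and rejected with a diagnostic if infeasible.

TILs are emitted as decile bins (0-9 meaning 0-9%, ..., 90-100%): the
pre-treatment true decile is uniform on 2-7 and the true decile change is a
monotone quantile map of its latent into {-2..1} for designated
non-responders and {2, 3} for responders, calibrated so the responder
fraction matches the request; two pathologist reads are the true decile plus
rounded Gaussian reader noise. The expression matrix carries housekeeping
genes with no group effect and signature genes shifted up by
``activation_effect`` (log2 units) in immune-activated patients, with a
per-patient random profile (shared by that patient's pre and post samples)
and independent per-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import default_signature_sets
from .tme import TilRecord, build_til_records

__all__ = ["CohortSpec", "Cohort", "make_cohort", "DEFAULT_TARGET_CORRELATIONS"]

#: headline study conditions: feature vs TIL-quantity Spearman targets
DEFAULT_TARGET_CORRELATIONS: dict[tuple[str, str], float] = {
    ("delta_pe", "delta_til"): -0.69,
    ("pre_adc", "delta_til"): -0.67,
    ("pre_wf", "delta_til"): 0.51,
    ("pre_pe", "delta_til"): 0.48,
}

FEATURE_NAMES = ["ftv", "wf", "ser", "pe", "adc"]
TIL_LATENTS = ["pre_til", "delta_til"]

#: (mean, sd) marginals per latent feature; magnitudes follow typical
#: HER2+ breast lesions (FTV cc, WF fraction, SER unitless, PE %, ADC mm^2/s)
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "pre_ftv": (3.0, 1.5), "delta_ftv": (0.5, 1.5),
    "pre_wf": (0.35, 0.12), "delta_wf": (0.0, 0.10),
    "pre_ser": (1.8, 0.3), "delta_ser": (0.0, 0.25),
    "pre_pe": (200.0, 40.0), "delta_pe": (-10.0, 25.0),
    "pre_adc": (0.92e-3, 0.15e-3), "delta_adc": (0.05e-3, 0.10e-3),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 14
    target_correlations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    frac_responders: float = 6 / 13
    n_missing_post: int = 1  # patients lacking post-treatment tissue
    n_genes: int = 120
    n_housekeepers: int = 10
    signature_defs: Mapping[str, Sequence[str]] | None = None  # default: toy immune sets
    activation_effect: float = 2.0  # log2 shift of signature genes in activated patients
    noise_sd: float = 0.5  # residual per-sample log2 noise
    patient_sd: float = 1.0  # per-patient gene profile, shared across timepoints
    treatment_sd: float = 0.25  # per-patient gene shift applied to post samples
    library_sd: float = 0.3  # per-sample global scale (removed by normalization)
    reader_sd: float = 0.5  # pathologist read noise, deciles
    activation_flip_prob: float = 0.0  # decouples activation label from TIL response
    marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.frac_responders <= 1:
            raise ValueError("frac_responders must be in [0, 1]")
        if not 0 <= self.n_missing_post <= self.n_patients:
            raise ValueError("n_missing_post out of range")
        if self.n_housekeepers < 2:
            raise ValueError("need at least two housekeeping genes")
        for pair, rho in self.target_correlations.items():
            if abs(rho) > 1:
                raise ValueError(f"target correlation {pair} = {rho} outside [-1, 1]")
        if self.reader_sd < 0 or self.noise_sd < 0 or self.patient_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    def gene_sets(self) -> dict[str, list[str]]:
        if self.signature_defs is not None:
            return {k: list(v) for k, v in self.signature_defs.items()}
        return default_signature_sets()


@dataclass
class Cohort:
    """All synthetic tables for one cohort, plus ground truth."""

    features: pd.DataFrame  # patient x {pre,post}_{ftv,wf,ser,pe,adc}
    tils_long: pd.DataFrame  # patient, timepoint, reader, decile
    til_records: list[TilRecord]
    expression: pd.DataFrame  # genes x samples (natural scale)
    housekeepers: list[str]
    gene_sets: dict[str, list[str]]
    sample_annotations: pd.DataFrame  # sample -> patient, timepoint, er_status, activated
    truth: pd.DataFrame  # patient-level ground truth
    spec: CohortSpec

    def til_summary(self) -> pd.DataFrame:
        """Per-patient combined deciles and their change, from the dual reads."""
        rows = {}
        for rec in self.til_records:
            rows[rec.patient] = {
                "pre_til": rec.pre_combined,
                "post_til": rec.post_combined,
                "delta_til": rec.delta_til,
            }
        return pd.DataFrame(rows).T.astype(float)


def _til_attenuation(spec: CohortSpec, til_quantity: str, m: int = 40000) -> float:
    """Rank attenuation of a TIL quantity's marginal pipeline.

    Decile binning, boundary clipping and dual-read noise all shrink the
    Spearman correlation an observed TIL quantity can carry relative to its
    Gaussian latent. This measures that shrinkage once on a large fixed
    internal sample so the latent correlation can be inflated to compensate;
    the calibration sample is independent of the cohort draw.
    """
    rng = np.random.default_rng(202310)  # calibration-only stream
    w = rng.standard_normal(m)
    u = norm.cdf(w)
    pre = np.minimum(2 + (norm.cdf(rng.standard_normal(m)) * 6).astype(int), 7)

    def _combined(true: np.ndarray) -> np.ndarray:
        reads = np.clip(np.rint(true[None, :] + rng.normal(0, spec.reader_sd, (2, m))), 0, 9)
        return reads.mean(axis=0)

    if til_quantity == "pre_til":
        true_pre = np.minimum(2 + (u * 6).astype(int), 7)
        obs = _combined(true_pre)
    elif til_quantity == "delta_til":
        delta = _delta_deciles_from_uniform(u, spec.frac_responders)
        post = np.clip(pre + delta, 0, 9)
        obs = _combined(post) - _combined(pre)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(til_quantity)
    if np.ptp(obs) == 0:  # e.g. frac_responders at a boundary with no read noise
        return 1.0
    from scipy.stats import spearmanr

    return float(spearmanr(w, obs).statistic)


def _latent_correlation(spec: CohortSpec) -> tuple[list[str], np.ndarray]:
    """Latent variable list and their Pearson correlation matrix."""
    names = [f"{tp}_{f}" for f in FEATURE_NAMES for tp in ("pre", "delta")] + TIL_LATENTS
    pos = {n: i for i, n in enumerate(names)}
    k = len(names)
    C = np.eye(k)

    atten = {t: None for t in TIL_LATENTS}
    loadings: dict[str, dict[str, float]] = {t: {} for t in TIL_LATENTS}
    for (var, til), rho in spec.target_correlations.items():
        if var not in pos:
            raise ValueError(f"unknown feature variable {var!r} in target_correlations")
        if til not in TIL_LATENTS:
            raise ValueError(f"unknown TIL quantity {til!r} in target_correlations "
                             f"(supported: {TIL_LATENTS})")
        if atten[til] is None:
            atten[til] = _til_attenuation(spec, til)
        rho_lat = rho / atten[til]
        if abs(rho_lat) >= 1.0:
            raise ValueError(
                f"target Spearman {rho} for ({var}, {til}) is unreachable after decile "
                f"binning and reader noise (attenuation {atten[til]:.3f}); lower the "
                "target or the reader noise"
            )
        r = 2.0 * np.sin(np.pi * rho_lat / 6.0)  # Spearman -> latent Pearson
        C[pos[var], pos[til]] = C[pos[til], pos[var]] = r
        if til in loadings:
            loadings[til][var] = r

    # one-factor completion among features sharing a TIL quantity
    for til, load in loadings.items():
        vars_ = list(load)
        for i, a in enumerate(vars_):
            for b in vars_[i + 1:]:
                if C[pos[a], pos[b]] == 0.0:
                    C[pos[a], pos[b]] = C[pos[b], pos[a]] = load[a] * load[b]

    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-10:
        raise ValueError(
            "target_correlations are jointly infeasible: latent correlation matrix "
            f"has minimum eigenvalue {eigmin:.4g} < 0; reduce the magnitudes or "
            "spread targets over fewer variables"
        )
    return names, C


def _delta_deciles_from_uniform(u: np.ndarray, frac_responders: float) -> np.ndarray:
    """Monotone quantile map of latent uniforms to true decile changes.

    The upper ``frac_responders`` tail maps to {+2, +3}; the rest to
    {-2, -1, 0, +1}. Monotone, so Spearman against other latents is kept.
    """
    q = 1.0 - frac_responders
    delta = np.empty(len(u), dtype=int)
    lower = u < q
    if q > 0:
        delta[lower] = -2 + np.minimum((u[lower] / q * 4).astype(int), 3)
    if frac_responders > 0:
        delta[~lower] = 2 + np.minimum(((u[~lower] - q) / max(frac_responders, 1e-12) * 2)
                                       .astype(int), 1)
    return delta


def make_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Draw one synthetic cohort under ``spec`` (fully seeded)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names, C = _latent_correlation(spec)
    n = spec.n_patients

    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(names)))
    Z = rng.standard_normal((n, len(names))) @ L.T
    z = pd.DataFrame(Z, columns=names)
    width = max(2, len(str(n)))
    patients = [f"P{i + 1:0{width}d}" for i in range(n)]

    # --- imaging features: Gaussian marginals, post = pre + delta ---
    feat = pd.DataFrame(index=patients)
    for f in FEATURE_NAMES:
        mu_pre, sd_pre = spec.marginals[f"pre_{f}"]
        mu_d, sd_d = spec.marginals[f"delta_{f}"]
        pre = mu_pre + sd_pre * z[f"pre_{f}"].to_numpy()
        post = pre + mu_d + sd_d * z[f"delta_{f}"].to_numpy()
        if f == "wf":
            pre, post = np.clip(pre, 0, 1), np.clip(post, 0, 1)
        elif f in ("ftv", "pe"):
            pre, post = np.clip(pre, 0, None), np.clip(post, 0, None)
        elif f == "adc":
            pre, post = np.clip(pre, 1e-5, None), np.clip(post, 1e-5, None)
        feat[f"pre_{f}"] = pre
        feat[f"post_{f}"] = post

    # --- TIL deciles and dual reads ---
    u_pre = norm.cdf(z["pre_til"].to_numpy())
    true_pre = np.minimum(2 + (u_pre * 6).astype(int), 7)
    u_delta = norm.cdf(z["delta_til"].to_numpy())
    true_delta = _delta_deciles_from_uniform(u_delta, spec.frac_responders)
    true_post = np.clip(true_pre + true_delta, 0, 9)
    responder_true = true_delta > 1

    missing_post = set(rng.choice(n, size=spec.n_missing_post, replace=False).tolist())
    rows = []
    for i, pat in enumerate(patients):
        for tp, true in (("pre", true_pre[i]), ("post", true_post[i])):
            if tp == "post" and i in missing_post:
                continue
            for reader in (1, 2):
                noisy = int(np.clip(np.rint(true + rng.normal(0, spec.reader_sd)), 0, 9))
                rows.append({"patient": pat, "timepoint": tp, "reader": reader,
                             "decile": noisy})
    tils_long = pd.DataFrame(rows)
    til_records = build_til_records(tils_long)

    # --- activation labels and expression matrix ---
    flips = rng.random(n) < spec.activation_flip_prob
    activated = responder_true ^ flips

    gene_sets = spec.gene_sets()
    hk = [f"HK{i + 1:02d}" for i in range(spec.n_housekeepers)]
    sig_genes = sorted({g for gs in gene_sets.values() for g in gs})
    n_filler = spec.n_genes - spec.n_housekeepers - len(sig_genes)
    if n_filler < 0:
        raise ValueError(
            f"n_genes = {spec.n_genes} too small for {spec.n_housekeepers} housekeepers "
            f"plus {len(sig_genes)} signature genes"
        )
    filler = [f"BG{i + 1:03d}" for i in range(n_filler)]
    genes = hk + sig_genes + filler
    in_sig = np.array([g in set(sig_genes) for g in genes])
    is_hk = np.array([g in set(hk) for g in genes])

    samples, sample_patient, sample_tp = [], [], []
    for i, pat in enumerate(patients):
        for tp in ("pre", "post"):
            if tp == "post" and i in missing_post:
                continue
            samples.append(f"{pat}_{tp}")
            sample_patient.append(i)
            sample_tp.append(tp)

    mu_g = np.where(is_hk, rng.normal(10.0, 0.5, len(genes)),
                    rng.normal(8.0, 1.0, len(genes)))
    patient_profile = rng.normal(0.0, spec.patient_sd, (n, len(genes)))
    patient_profile[:, is_hk] = 0.0
    treatment_profile = rng.normal(0.0, spec.treatment_sd, (n, len(genes)))
    treatment_profile[:, is_hk] = 0.0
    library = rng.normal(0.0, spec.library_sd, len(samples))

    log2vals = np.empty((len(genes), len(samples)))
    for j, (pi, tp) in enumerate(zip(sample_patient, sample_tp)):
        v = mu_g + library[j] + patient_profile[pi]
        if tp == "post":
            v = v + treatment_profile[pi]
        v = v + np.where(in_sig & ~is_hk, spec.activation_effect * activated[pi], 0.0)
        noise = rng.normal(0.0, spec.noise_sd, len(genes))
        noise[is_hk] = rng.normal(0.0, 0.05, int(is_hk.sum()))
        log2vals[:, j] = v + noise
    expression = pd.DataFrame(2.0 ** log2vals, index=genes, columns=samples)

    er_positive = rng.permutation(n) < n // 2
    sample_annotations = pd.DataFrame(
        {
            "patient": [patients[i] for i in sample_patient],
            "timepoint": sample_tp,
            "er_status": ["positive" if er_positive[i] else "negative" for i in sample_patient],
            "activated": [bool(activated[i]) for i in sample_patient],
        },
        index=samples,
    )
    truth = pd.DataFrame(
        {
            "true_pre_til": true_pre,
            "true_delta_til": true_delta,
            "true_post_til": true_post,
            "responder_true": responder_true,
            "activated": activated,
            "er_positive": er_positive,
            "missing_post": [i in missing_post for i in range(n)],
        },
        index=patients,
    )
    return Cohort(
        features=feat,
        tils_long=tils_long,
        til_records=til_records,
        expression=expression,
        housekeepers=hk,
        gene_sets=gene_sets,
        sample_annotations=sample_annotations,
        truth=truth,
        spec=spec,
    )
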