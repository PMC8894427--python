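"""Discriminant analysis of principal components and transplant-shift
inference.

The discriminant space is built from the two non-transplanted (home) lines
only: features are centered, projected onto the top principal components,
and a single linear discriminant axis (two groups) is computed as the
pooled-within-covariance inverse times the group-mean difference.
Transplanted samples are then projected into this space and the magnitude and
significance of their movement toward the destination profile is inferred
with a conjugate Gibbs sampler for a Gaussian linear model with a
replicate-culture random intercept. Sign-crossing posterior p-values are
floored at 1/n_draws, so a shift with no crossings is reported at the floor
(e.g. 4e-04 with 2500 draws).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import stage_rng
from .io import SampleDesign

_RIDGE = 1e-8


@dataclass
class DAPCModel:
    center: np.ndarray          # feature means of the home samples
    rotation: np.ndarray        # (n_features, n_pcs)
    variance_fraction: float    # PCA variance retained by the n_pcs
    loading: np.ndarray         # (n_pcs,) unit discriminant axis
    group_labels: tuple
    group_means: np.ndarray     # (2,) home-group means on the axis
    within_sd: float            # pooled within-group SD on the axis
    separable: bool = True

    @property
    def n_pcs(self) -> int:
        return self.rotation.shape[1]


def fit_dapc(features: np.ndarray, groups, n_pcs: int) -> DAPCModel:
    """Fit PCA + one-axis linear discriminant on the home samples.

    ``features`` is (n_samples, n_features); ``groups`` has exactly two
    levels with >= 2 samples each. A tiny ridge keeps the within-group
    covariance invertible; if the groups coincide the model is flagged
    non-separable.
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    labels = tuple(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError("need >= 2 samples per group")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_pcs < 1 or n_pcs > rank:
        raise ValueError(f"n_pcs must be in [1, {rank}]")
    rotation = Vt[:n_pcs].T
    var_frac = float((s[:n_pcs] ** 2).sum() / (s**2).sum())
    scores = Xc @ rotation

    m = [scores[groups == lab].mean(axis=0) for lab in labels]
    W = np.zeros((n_pcs, n_pcs))
    dof = 0
    for lab, mu in zip(labels, m):
        d = scores[groups == lab] - mu
        W += d.T @ d
        dof += (groups == lab).sum() - 1
    W /= max(dof, 1)
    W += _RIDGE * np.eye(n_pcs)
    axis = np.linalg.solve(W, m[1] - m[0])
    norm = np.linalg.norm(axis)
    separable = bool(norm > 1e-6 and np.linalg.norm(m[1] - m[0]) > 1e-9)
    axis = axis / norm if norm > 0 else axis
    coords = scores @ axis
    gmeans = np.array([coords[groups == lab].mean() for lab in labels])
    wvar = 0.0
    for lab, gm in zip(labels, gmeans):
        d = coords[groups == lab] - gm
        wvar += (d**2).sum()
    within_sd = float(np.sqrt(wvar / max(dof, 1)))
    return DAPCModel(center, rotation, var_frac, axis, labels, gmeans,
                     within_sd, separable)


def project(model: DAPCModel, samples: np.ndarray) -> np.ndarray:
    """Discriminant coordinates for new samples (affine in the features)."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[1] != model.center.shape[0]:
        raise ValueError("feature dimension mismatch")
    return ((X - model.center) @ model.rotation) @ model.loading


def dapc_coordinates(features: np.ndarray, design: SampleDesign,
                     generation: str, n_pcs: int) -> tuple[pd.DataFrame, DAPCModel]:
    """Fit on home lines of one generation, project all of its samples."""
    home = design.mask(generation=generation) & (
        design.table["line"] == design.table["environment"]).to_numpy()
    if home.sum() < 4:
        raise ValueError("need >= 2 home samples per line")
    model = fit_dapc(features[home], design.table.loc[home, "line"].to_numpy(), n_pcs)
    gen_mask = design.mask(generation=generation)
    coords = project(model, features[gen_mask])
    out = design.table.loc[gen_mask, ["sample_id", "line", "environment",
                                      "generation", "replicate"]].copy()
    out["coordinate"] = coords
    return out.reset_index(drop=True), model


# ---------------------------------------------------------------------------
# Gibbs sampler for the transplant-shift model


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor on a single chain."""
    n = len(draws) // 2
    halves = np.stack([draws[:n], draws[n:2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((w * (n - 1) / n + b / n) / w))


def shift_inference(coords: pd.DataFrame, n_draws: int = 2500,
                    burn_in: int = 500, seed: int = 0) -> dict:
    """Posterior inference on transplant-induced movement along the axis.

    Model: coordinate = b0 + b_line*[line==OWA] + b_tAM*[AM transplanted]
    + b_tOWA*[OWA transplanted] + u_culture + e, with u_culture a random
    intercept per replicate culture (line x replicate) and conjugate
    normal/inverse-gamma priors, sampled by Gibbs. Reports per-line transplant
    effects and the posterior of |shift_AM| - |shift_OWA| with sign-crossing
    p-values floored at 1/n_draws.
    """
    t = coords
    for col in ("line", "environment", "replicate", "coordinate"):
        if col not in t.columns:
            raise ValueError(f"coordinates table missing column {col}")
    cells = t.groupby(["line", "environment"])["replicate"].nunique()
    if (cells < 2).any():
        raise ValueError("need >= 2 replicates per line x environment cell")
    y = t["coordinate"].to_numpy(dtype=float)
    is_owa = (t["line"] == "OWA").to_numpy()
    transplant = (t["line"] != t["environment"]).to_numpy()
    X = np.column_stack([
        np.ones(len(y)),
        is_owa.astype(float),
        (transplant & ~is_owa).astype(float),
        (transplant & is_owa).astype(float),
    ])
    culture = pd.factorize(t["line"].astype(str) + "_" + t["replicate"].astype(str))[0]
    n_cult = culture.max() + 1
    Z = np.zeros((len(y), n_cult))
    Z[np.arange(len(y)), culture] = 1.0

    rng = stage_rng(seed, "shift_inference")
    p = X.shape[1]
    prior_prec = 1e-4  # N(0, 100^2) on fixed effects
    a0 = b0 = 1e-3     # IG priors on both variances
    beta = np.zeros(p)
    u = np.zeros(n_cult)
    sig2_e = float(np.var(y)) or 1.0
    sig2_u = sig2_e
    XtX = X.T @ X
    total = burn_in + n_draws
    keep_beta = np.empty((n_draws, p))
    for it in range(total):
        # fixed effects | rest
        prec = XtX / sig2_e + prior_prec * np.eye(p)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ (y - Z @ u)) / sig2_e
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        # random intercepts | rest
        resid = y - X @ beta
        nj = Z.sum(axis=0)
        prec_u = nj / sig2_e + 1.0 / sig2_u
        mean_u = (Z.T @ resid / sig2_e) / prec_u
        u = rng.normal(mean_u, np.sqrt(1.0 / prec_u))
        # variances | rest
        e = resid - Z @ u
        sig2_e = 1.0 / rng.gamma(a0 + len(y) / 2, 1.0 / (b0 + (e**2).sum() / 2))
        sig2_u = 1.0 / rng.gamma(a0 + n_cult / 2, 1.0 / (b0 + (u**2).sum() / 2))
        if it >= burn_in:
            keep_beta[it - burn_in] = beta

    floor = 1.0 / n_draws

    def _summary(draws: np.ndarray) -> dict:
        lo, hi = np.quantile(draws, [0.025, 0.975])
        p_sign = 2.0 * min((draws > 0).mean(), (draws < 0).mean())
        return {"mean": float(draws.mean()), "ci_low": float(lo),
                "ci_high": float(hi), "p_mcmc": float(max(p_sign, floor)),
                "at_floor": bool(p_sign < floor or p_sign == 0.0)}

    shift_am = keep_beta[:, 2]
    shift_owa = keep_beta[:, 3]
    mag_diff = np.abs(shift_am) - np.abs(shift_owa)
    rhat = max(_split_rhat(shift_am), _split_rhat(shift_owa))
    return {
        "AM": _summary(shift_am),
        "OWA": _summary(shift_owa),
        "magnitude_difference": _summary(mag_diff),
        "n_draws": n_draws,
        "p_floor": floor,
        "rhat": rhat,
        "converged": rhat <= 1.1,
    }
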