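"""Probe-intensity preprocessing.

Raw bead intensities are modelled as observed = B + S with background
B ~ Normal(mu_b, sigma_b^2) and signal S ~ Exponential(mean alpha)
("normexp" convolution).  Background correction replaces each observed
value by E[S | observed], which is always positive; arrays are then put on
a common distribution by quantile normalization, undetected probes are
filtered on their detection scores, and probes overlapping strain sequence
variants are excluded before any genetic analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormexpParams:
    """Fitted normexp convolution parameters."""

    bg_mean: float    # mu_b
    bg_sd: float      # sigma_b
    signal_mean: float  # alpha (mean of the exponential signal)

    def __post_init__(self):
        if not (self.bg_sd > 0 and self.signal_mean > 0):
            raise ValueError("bg_sd and signal_mean must be positive")


def _normexp_nll(theta, x):
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = -np.log(alpha) + sigma**2 / (2 * alpha**2) - (x - mu) / alpha + stats.norm.logcdf(z)
    return -np.sum(ll)


def _moment_start(x):
    m, v = np.mean(x), np.var(x)
    skew = stats.skew(x)
    alpha = (max(skew, 1e-3) * v**1.5 / 2.0) ** (1.0 / 3.0)
    sigma2 = max(v - alpha**2, 0.01 * v)
    return np.array([m - alpha, 0.5 * np.log(sigma2), np.log(alpha)])


def normexp_fit(values) -> NormexpParams:
    """Maximum-likelihood fit of the Normal+Exponential convolution.

    Initialized by the method of moments (mean = mu + alpha,
    var = sigma^2 + alpha^2, skewness = 2 alpha^3 / var^1.5), then refined
    by Nelder-Mead on (mu, log sigma, log alpha).  The likelihood at the
    solution is never below the starting point.
    """
    x = np.asarray(values, float).ravel()
    if len(x) < 100:
        raise ValueError("normexp_fit needs at least 100 intensity values")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")
    if np.var(x) <= 0:
        raise ValueError("degenerate input: zero variance")

    theta0 = _moment_start(x)
    res = optimize.minimize(
        _normexp_nll, theta0, args=(x,), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    theta = res.x if _normexp_nll(res.x, x) <= _normexp_nll(theta0, x) else theta0
    return NormexpParams(float(theta[0]), float(np.exp(theta[1])), float(np.exp(theta[2])))


def normexp_correct(x, params: NormexpParams):
    """Background-corrected intensity E[signal | observed = x].

    With mu_s = x - mu_b - sigma_b^2/alpha and z = mu_s/sigma_b, the
    conditional mean of the exponential signal is
    mu_s + sigma_b * phi(z) / Phi(z), evaluated via log-densities so the
    far-left tail (x far below the background mean) stays finite and the
    result is strictly positive for any finite x.
    """
    x = np.asarray(x, float)
    mu_s = x - params.bg_mean - params.bg_sd**2 / params.signal_mean
    z = mu_s / params.bg_sd
    corrected = mu_s + params.bg_sd * np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return corrected if corrected.ndim else float(corrected)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (array) onto the mean empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    tied values within a column receive the mean of their reference
    quantiles.  Idempotent, and shape/order preserving.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("quantile normalization requires a complete matrix")
    X = matrix.to_numpy(float)
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # ties share the mean of their reference quantiles
        ser = pd.Series(mapped)
        out[:, j] = ser.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    matrix: pd.DataFrame,
    detection: pd.DataFrame,
    score_threshold: float = 0.5,
    sample_fraction: float = 0.5,
) -> pd.DataFrame:
    """Drop probes detecting only background signal.

    A probe is removed when its detection score falls below
    ``score_threshold`` in strictly more than ``sample_fraction`` of the
    samples (defaults reproduce the rule: score < 0.5 in > 50% of samples).
    """
    if detection is None:
        raise ValueError("detection scores are required")
    det = detection.loc[matrix.index, matrix.columns]
    if det.isna().to_numpy().any():
        raise ValueError("detection scores contain missing values")
    frac_low = (det.to_numpy() < score_threshold).mean(axis=1)
    keep = frac_low <= sample_fraction
    log.info("detection filter removed %d of %d probes", int((~keep).sum()), len(keep))
    return matrix.loc[keep]


def exclude_snp_probes(matrix: pd.DataFrame, exclusion_list) -> pd.DataFrame:
    """Remove probes whose target sequence carries strain DNA variants.

    Such probes hybridize allele-dependently and produce spurious cis-eQTL
    signal, so they are excluded before scanning.  Unknown identifiers are
    logged as warnings, not errors.
    """
    ids = set(exclusion_list)
    unknown = ids - set(matrix.index)
    if unknown:
        log.warning("%d exclusion-list ids not in the matrix: %s",
                    len(unknown), sorted(unknown)[:10])
    keep = ~matrix.index.isin(ids)
    log.info("excluded %d SNP-carrying probes", int((~keep).sum()))
    out = matrix.loc[keep]
    if out.empty:
        log.warning("exclusion list removed every probe")
    return out


def preprocess(
    raw: pd.DataFrame,
    detection: pd.DataFrame | None = None,
    exclusion_list=(),
    score_threshold: float = 0.5,
    sample_fraction: float = 0.5,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Full preprocessing chain: per-array normexp correction, quantile
    normalization, optional log2, detection filter, SNP-probe exclusion."""
    corrected = raw.copy()
    for col in raw.columns:
        params = normexp_fit(raw[col].to_numpy())
        corrected[col] = normexp_correct(raw[col].to_numpy(), params)
    normed = quantile_normalize(corrected)
    if log2_transform:
        normed = np.log2(normed.clip(lower=2.0**-10))
    if detection is not None:
        normed = detection_filter(normed, detection, score_threshold, sample_fraction)
    if len(exclusion_list):
        normed = exclude_snp_probes(normed, exclusion_list)
    return normed
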