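"""Beta values, detection p-values and the four normalization routes.

The methylation level of a locus is beta = M / (M + U), the methylated
share of the two-channel signal, in [0, 1].  Background correction
subtracts the per-sample mean of the built-in negative-control beads from
both channels (floored at zero), and quantile normalization maps every
sample's beta distribution onto the common mean-of-order-statistics
reference.  Crossing the two binary choices gives the four routes whose
differential-methylation calls are later intersected: raw, raw+quantile,
background, background+quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import IntensityStudy

__all__ = [
    "BetaMatrix",
    "ROUTES",
    "compute_beta",
    "background_normalize",
    "detection_p",
    "quantile_normalize_beta",
    "four_route_betas",
]

log = logging.getLogger(__name__)

ROUTES = ("raw", "raw+quantile", "background", "background+quantile")


@dataclass
class BetaMatrix:
    """Loci x samples beta values tagged with the normalization route."""

    values: pd.DataFrame
    route: str = "raw"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")


def compute_beta(M: pd.DataFrame, U: pd.DataFrame, route: str = "raw") -> BetaMatrix:
    """beta = M / (M + U); entries with zero total signal become missing."""
    m = M.to_numpy(dtype=float)
    u = U.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    return BetaMatrix(pd.DataFrame(beta, index=M.index, columns=M.columns), route=route)


def background_normalize(study: IntensityStudy) -> IntensityStudy:
    """Subtract each sample's mean negative-control signal from both channels.

    Corrected intensities are floored at zero.  Negative-control signals are
    corrected the same way, so their corrected mean is zero by construction.
    """
    neg = study.negatives
    for s in study.samples.index:
        if s not in neg.columns or neg[s].dropna().size < 2:
            raise ValueError(f"sample {s!r} has fewer than 2 negative-control values")
    bg = neg.mean(axis=0)
    M = (study.M - bg).clip(lower=0.0)
    U = (study.U - bg).clip(lower=0.0)
    negatives = neg - bg
    return IntensityStudy(M=M, U=U, negatives=negatives, samples=study.samples, manifest=study.manifest)


def detection_p(study: IntensityStudy) -> pd.DataFrame:
    """One-sided p that each locus's total signal exceeds the no-target level.

    The total signal M + U is compared against the per-sample empirical mean
    and standard deviation of the negative controls with a z approximation;
    a locus is "detected" at p < 0.05.
    """
    total = study.M.to_numpy(dtype=float) + study.U.to_numpy(dtype=float)
    mu = study.negatives.mean(axis=0).to_numpy()
    sd = study.negatives.std(axis=0, ddof=1).to_numpy()
    p = np.empty_like(total)
    for j in range(total.shape[1]):
        if sd[j] == 0:
            log.warning("zero negative-control variance in sample %s", study.M.columns[j])
            p[:, j] = np.where(total[:, j] > mu[j], 0.0, 1.0)
        else:
            p[:, j] = stats.norm.sf((total[:, j] - mu[j]) / sd[j])
    return pd.DataFrame(p, index=study.M.index, columns=study.M.columns)


def quantile_normalize_beta(beta: BetaMatrix, max_missing_frac: float = 0.05) -> BetaMatrix:
    """Map every sample onto the mean-of-order-statistics reference.

    Missing entries are imputed with the sample median for ranking, then
    restored as missing.  Ties within a sample receive the average of the
    tied reference values (via interpolation at average ranks), which keeps
    the transform idempotent.  A single-sample matrix is returned unchanged.
    """
    values = beta.values.to_numpy(dtype=float).copy()
    n_loci, n_samples = values.shape
    if n_samples < 2:
        log.info("quantile normalization on a single sample is the identity")
        return BetaMatrix(beta.values.copy(), route=beta.route + "+quantile")
    missing = ~np.isfinite(values)
    if missing.mean(axis=0).max() > max_missing_frac:
        raise ValueError(f"more than {max_missing_frac:.0%} missing values in a sample")
    if missing.any():
        med = np.nanmedian(values, axis=0)
        values = np.where(missing, med[None, :], values)

    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n_loci + 1, dtype=float)
    for j in range(n_samples):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    out[missing] = np.nan
    suffix = "" if beta.route.endswith("+quantile") else "+quantile"
    return BetaMatrix(pd.DataFrame(out, index=beta.values.index, columns=beta.values.columns),
                      route=beta.route + suffix)


def four_route_betas(study: IntensityStudy) -> dict[str, BetaMatrix]:
    """The four normalization routes, keyed and tagged by route name."""
    raw = compute_beta(study.M, study.U, route="raw")
    bg_study = background_normalize(study)
    background = compute_beta(bg_study.M, bg_study.U, route="background")
    routes = {
        "raw": raw,
        "raw+quantile": quantile_normalize_beta(raw),
        "background": background,
        "background+quantile": quantile_normalize_beta(background),
    }
    return routes
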