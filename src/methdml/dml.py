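"""Differentially methylated locus (DML) calling.

Two per-locus models are run side by side, mirroring common chip practice:

* a univariate, unpaired model giving a signed DiffScore,
  ``10 * sign(delta_beta) * (-log10 p)`` with a Welch two-sample t p-value,
  so |DiffScore| >= 30 corresponds exactly to p <= 0.001; and
* a mixed-model multi-way ANOVA with tissue, sex and location as fixed
  factors and case as a random factor (sex and location are constant within
  a case and therefore tested in the between-case stratum), with variance
  components by the method of moments and per-factor variance fractions on
  the sum-of-squares scale.

Calls require both an effect size (|delta beta| >= 0.2 by default) and an
FDR threshold (Benjamini-Hochberg q <= 0.01), and the consensus is the
direction-respecting intersection of the calls from the four normalization
routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .anova import SequentialAnova, paired_design_anova
from .preprocess import ROUTES, BetaMatrix

__all__ = [
    "LocusResult",
    "DMLCall",
    "SexScreen",
    "illumina_diffscore",
    "fit_locus_mixed_anova",
    "fit_all_loci",
    "bh_fdr",
    "call_dml",
    "consensus_dml",
    "sex_screen",
]

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300
DEFAULT_FACTORS = ("tissue", "sex", "location", "case")


@dataclass
class LocusResult:
    locus_id: str
    delta_beta: float
    diffscore: float
    f: dict[str, float]
    p: dict[str, float]
    variance_fractions: dict[str, float]
    variance_components: dict[str, float] = field(default_factory=dict)


@dataclass
class DMLCall:
    hyper: frozenset
    hypo: frozenset
    delta_beta_min: float
    fdr_q: float
    route: str

    def __post_init__(self) -> None:
        if self.hyper & self.hypo:
            raise ValueError("a locus cannot be both hyper- and hypomethylated")

    @property
    def loci(self) -> frozenset:
        return self.hyper | self.hypo


@dataclass
class SexScreen:
    significant: pd.DataFrame  # index locus_id; q, chromosome
    chromosome_counts: pd.Series
    autosomal_manifest: pd.DataFrame


def _welch(beta: np.ndarray, group_a: np.ndarray, group_b: np.ndarray):
    """Row-wise Welch t p and mean difference a - b, with degenerate handling."""
    a = beta[:, group_a]
    b = beta[:, group_b]
    delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: equal means -> no evidence (p=1); unequal -> p=0
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(delta) > 0)] = 0.0
    p[degenerate & (np.abs(delta) == 0)] = 1.0
    return p, delta


def illumina_diffscore(beta_row, is_tumor) -> tuple[float, float, float]:
    """Signed significance score for one locus: 10*sign(delta)*(-log10 p).

    ``is_tumor`` is a boolean mask over the samples of ``beta_row``; delta
    beta is tumor minus normal.  |score| >= 30 corresponds to p <= 0.001.
    """
    row = np.asarray(beta_row, dtype=float)[None, :]
    mask = np.asarray(is_tumor, dtype=bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    p, delta = _welch(row, mask, ~mask)
    p_f, delta_f = float(p[0]), float(delta[0])
    score = 0.0 if p_f >= 1.0 else 10.0 * np.sign(delta_f) * (-np.log10(max(p_f, _P_FLOOR)))
    return score, p_f, delta_f


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fit_all_loci(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    min_complete_cases: int = 3,
) -> pd.DataFrame:
    """Per-locus mixed-model ANOVA over a whole beta matrix, vectorized.

    Returns one row per locus with delta_beta, diffscore, per-factor F/p,
    BH q for the tissue and sex factors, variance fractions summing to 1,
    and method-of-moments variance components for the case effect and the
    residual.  Loci with missing values are refit on their complete samples
    (skipped, with every statistic missing, below ``min_complete_cases``
    complete tumor/normal pairs).
    """
    values = (beta.values if isinstance(beta, BetaMatrix) else beta)
    Y = values.to_numpy(dtype=float)
    index = values.index
    cols = values.columns
    samples = samples.loc[cols]
    is_tumor = (samples["tissue"] == "tumor").to_numpy()

    p_welch, delta = _welch(Y, is_tumor, ~is_tumor)
    diffscore = np.where(
        p_welch >= 1.0, 0.0, 10.0 * np.sign(delta) * (-np.log10(np.maximum(p_welch, _P_FLOOR)))
    )

    out = pd.DataFrame(index=index)
    out["delta_beta"] = delta
    out["diffscore"] = diffscore

    complete = ~np.isnan(Y).any(axis=1)
    factor_cols = list(factors) + ["residual"]
    stats_store = {
        name: np.full(len(index), np.nan)
        for name in [f"F_{f}" for f in factors]
        + [f"p_{f}" for f in factors]
        + [f"frac_{f}" for f in factors]
        + ["frac_error", "varcomp_case", "varcomp_error"]
    }

    def _store(rows: np.ndarray, seq: SequentialAnova, ss, tests) -> None:
        total = ss["total"]
        usable = (total > 0) & ~ss["degenerate"]
        safe_total = np.where(usable, total, 1.0)
        for f in factors:
            F, p = tests[f]
            stats_store[f"F_{f}"][rows] = F
            stats_store[f"p_{f}"][rows] = p
            stats_store[f"frac_{f}"][rows] = np.where(usable, ss[f] / safe_total, 0.0)
        stats_store["frac_error"][rows] = np.where(usable, ss["residual"] / safe_total, 1.0)
        if "case" in factors and seq.df["case"] > 0 and seq.df["residual"] > 0:
            ms_case = ss["case"] / seq.df["case"]
            ms_res = ss["residual"] / seq.df["residual"]
            stats_store["varcomp_case"][rows] = np.maximum((ms_case - ms_res) / 2.0, 0.0)
            stats_store["varcomp_error"][rows] = ms_res

    if complete.any():
        seq, ss, tests = paired_design_anova(Y[complete], samples, factors)
        _store(np.flatnonzero(complete), seq, ss, tests)

    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(Y[i])
        sub = samples.loc[cols[ok]]
        pairs = sub.groupby("case_id")["tissue"].nunique()
        if (pairs == 2).sum() < min_complete_cases:
            log.info("locus %s skipped: fewer than %d complete cases", index[i], min_complete_cases)
            continue
        seq, ss, tests = paired_design_anova(Y[i][ok][None, :], sub, factors)
        _store(np.array([i]), seq, ss, tests)

    for name, arr in stats_store.items():
        out[name] = arr
    fitted = out["p_tissue"].notna()
    for f in (f for f in ("tissue", "sex") if f in factors):
        q = np.full(len(out), np.nan)
        if fitted.any():
            q[fitted.to_numpy()] = bh_fdr(out.loc[fitted, f"p_{f}"].to_numpy())
        out[f"q_{f}"] = q
    return out


def fit_locus_mixed_anova(
    beta_row,
    samples: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
    locus_id: str = "locus",
) -> LocusResult:
    """Mixed-model ANOVA for a single locus; see :func:`fit_all_loci`."""
    row = pd.DataFrame(
        np.asarray(beta_row, dtype=float)[None, :], index=[locus_id], columns=samples.index
    )
    table = fit_all_loci(row, samples, factors=factors).iloc[0]
    fracs = {f: float(table[f"frac_{f}"]) for f in factors}
    fracs["error"] = float(table["frac_error"])
    return LocusResult(
        locus_id=locus_id,
        delta_beta=float(table["delta_beta"]),
        diffscore=float(table["diffscore"]),
        f={f: float(table[f"F_{f}"]) for f in factors},
        p={f: float(table[f"p_{f}"]) for f in factors},
        variance_fractions=fracs,
        variance_components={
            "case": float(table["varcomp_case"]),
            "error": float(table["varcomp_error"]),
        },
    )


def call_dml(
    results: pd.DataFrame,
    delta_beta_min: float = 0.2,
    fdr_q: float = 0.01,
    route: str = "raw",
) -> DMLCall:
    """Threshold the per-locus table into hyper- and hypomethylated sets."""
    q = results["q_tissue"]
    d = results["delta_beta"]
    hyper = results.index[(q <= fdr_q) & (d >= delta_beta_min)]
    hypo = results.index[(q <= fdr_q) & (d <= -delta_beta_min)]
    return DMLCall(
        hyper=frozenset(hyper), hypo=frozenset(hypo),
        delta_beta_min=delta_beta_min, fdr_q=fdr_q, route=route,
    )


def consensus_dml(calls: dict[str, DMLCall] | list[DMLCall]) -> DMLCall:
    """Direction-respecting intersection of the four per-route call sets."""
    call_list = list(calls.values()) if isinstance(calls, dict) else list(calls)
    tags = sorted(c.route for c in call_list)
    if tags != sorted(ROUTES):
        raise ValueError(f"expected routes {sorted(ROUTES)}, got {tags}")
    hyper = frozenset.intersection(*[c.hyper for c in call_list])
    hypo = frozenset.intersection(*[c.hypo for c in call_list])
    first = call_list[0]
    return DMLCall(
        hyper=hyper, hypo=hypo,
        delta_beta_min=first.delta_beta_min, fdr_q=first.fdr_q, route="consensus",
    )


def sex_screen(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    manifest: pd.DataFrame,
    fdr_q: float = 0.01,
    results: pd.DataFrame | None = None,
) -> SexScreen:
    """Find sex-differential loci and restrict the manifest to autosomes.

    Whatever the outcome of the screen, all X/Y loci are removed from the
    returned manifest: X-inactivation makes sex-chromosome loci
    sex-differential, and leaving them in would contaminate tumor/normal
    calls.  Passing a precomputed ``results`` table avoids refitting.
    """
    if results is None:
        results = fit_all_loci(beta, samples)
    autosomal = manifest[~manifest["chromosome"].isin(["X", "Y"])]
    if samples["sex"].nunique() < 2:
        log.warning("single-sex study: sex screen is empty, autosome filter still applied")
        empty = pd.DataFrame(columns=["q_sex", "chromosome"])
        return SexScreen(empty, pd.Series(dtype=int), autosomal)
    sig_mask = results["q_sex"] <= fdr_q
    sig = results.loc[sig_mask, ["q_sex"]].join(manifest["chromosome"])
    counts = sig["chromosome"].value_counts()
    return SexScreen(sig, counts, autosomal)
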