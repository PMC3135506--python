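"""Sequential (type I) sum-of-squares engine for the paired-design mixed ANOVA.

The study design is 24 cases x 2 tissues on one chip batch: tissue is a
within-case fixed factor, sex and location are between-case fixed factors
(constant within a case, hence nested in the random case factor), and case
itself is random.  For such a design the residual stratum after fitting
tissue + sex + location + case *is* the tissue-by-case stratum, so the
tissue F is formed against the residual mean square, while sex and location
are tested against the between-case mean square.

The decomposition is computed by orthogonalising the factor design blocks
in a fixed order (Gram-Schmidt via SVD per block); per-factor sums of
squares are then squared projections ``||Y Q_f||^2``, which makes the whole
genome-wide fit a handful of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SequentialAnova", "build_blocks", "paired_design_anova"]

_TOL = 1e-9


def build_blocks(samples: pd.DataFrame, factors: tuple[str, ...]) -> list[tuple[str, np.ndarray]]:
    """Dummy-coded design blocks, one per factor, preceded by the grand mean.

    ``samples`` must carry one column per requested factor (``case`` maps to
    the ``case_id`` column).  Redundant columns (a between-case factor is
    linearly contained in the case dummies) are harmless: the sequential
    orthogonalisation assigns each factor only the dimensions not already
    spanned by earlier blocks, which is exactly the type I convention.
    """
    colmap = {"case": "case_id", "patient": "case_id", "sample": "sample_id"}
    n = len(samples)
    blocks: list[tuple[str, np.ndarray]] = [("mean", np.ones((n, 1)))]
    for f in factors:
        col = colmap.get(f, f)
        if col == "sample_id" and col not in samples.columns:
            values = samples.index.to_numpy()
        else:
            values = samples[col].to_numpy()
        dummies = pd.get_dummies(pd.Series(values)).to_numpy(dtype=float)
        blocks.append((f, dummies))
    return blocks


@dataclass
class SequentialAnova:
    """Orthonormal bases and degrees of freedom for an ordered factor list."""

    factors: tuple[str, ...]
    basis: dict[str, np.ndarray] = field(repr=False)
    df: dict[str, int]
    n: int

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, factors: tuple[str, ...]) -> "SequentialAnova":
        blocks = build_blocks(samples, factors)
        n = blocks[0][1].shape[0]
        acc: np.ndarray | None = None
        basis: dict[str, np.ndarray] = {}
        df: dict[str, int] = {}
        for name, X in blocks:
            resid = X if acc is None else X - acc @ (acc.T @ X)
            u, s, _ = np.linalg.svd(resid, full_matrices=False)
            keep = s > _TOL * max(1.0, s[0] if s.size else 0.0)
            q = u[:, keep]
            if name != "mean":
                basis[name] = q
                df[name] = q.shape[1]
            acc = q if acc is None else np.hstack([acc, q])
        model_df = 1 + sum(df.values())
        df["residual"] = n - model_df
        return cls(factors=factors, basis=basis, df=df, n=n)

    def decompose(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Per-row sums of squares for each factor, the residual and the total.

        ``Y`` is (n_rows, n_samples); rows are loci (or a single long response).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[None, :]
        centered = Y - Y.mean(axis=1, keepdims=True)
        ss_total = np.einsum("ij,ij->i", centered, centered)
        # a constant row has total SS at rounding-noise level, not exactly 0
        scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
        degenerate = ss_total <= Y.shape[1] * (1e-10 * scale) ** 2
        out: dict[str, np.ndarray] = {"total": ss_total, "degenerate": degenerate}
        explained = np.zeros_like(ss_total)
        for name in self.factors:
            proj = Y @ self.basis[name]
            ss = np.einsum("ij,ij->i", proj, proj)
            out[name] = ss
            explained += ss
        out["residual"] = np.maximum(ss_total - explained, 0.0)
        return out

    def f_tests(
        self, ss: dict[str, np.ndarray], strata: dict[str, str]
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """F statistic and p-value per factor against its error stratum.

        ``strata`` maps factor name -> denominator term ("residual" or another
        factor).  Degenerate rows (zero total or denominator variation) get
        F = 0, p = 1 when the numerator is also zero, F = inf, p = 0 otherwise.
        """
        results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for factor, denom in strata.items():
            df_num = self.df[factor]
            df_den = self.df[denom]
            if df_num == 0 or df_den == 0:
                zero = np.zeros_like(ss["total"])
                results[factor] = (zero, np.ones_like(zero))
                continue
            ms_num = ss[factor] / df_num
            ms_den = ss[denom] / df_den
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(ms_den > 0, ms_num / ms_den, np.where(ms_num > 0, np.inf, 0.0))
            p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_num, df_den), 0.0)
            p = np.where(F == 0.0, 1.0, p)
            if "degenerate" in ss:
                F = np.where(ss["degenerate"], 0.0, F)
                p = np.where(ss["degenerate"], 1.0, p)
            results[factor] = (F, p)
        return results


def paired_design_anova(
    Y: np.ndarray,
    samples: pd.DataFrame,
    factors: tuple[str, ...] = ("tissue", "sex", "location", "case"),
) -> tuple[SequentialAnova, dict[str, np.ndarray], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """One-call fit of the per-locus mixed model on complete data.

    Returns the decomposition object, the SS table and the F/p per factor with
    the paired-design strata: tissue (and case) against the residual
    tissue-by-case stratum, sex and location against the between-case stratum.
    """
    seq = SequentialAnova.from_samples(samples, factors)
    ss = seq.decompose(Y)
    strata: dict[str, str] = {}
    for f in factors:
        if f in ("sex", "location") and "case" in factors:
            strata[f] = "case"
        else:
            strata[f] = "residual"
    tests = seq.f_tests(ss, strata)
    return seq, ss, tests
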