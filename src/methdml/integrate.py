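"""Copy-number segmentation and methylation/expression/CN integration.

Copy-number profiles are segmented by recursive binary splitting: the
breakpoint with the smallest two-sample-t p between flanks is accepted if
p < 0.001 and both sides keep at least 10 markers, then each side is
segmented recursively.  Segments are called amplification (mean CN >= 2.5),
deletion (<= 1.5) or neutral, and per-sample calls are tested for
phenotype association with Pearson's chi-square.

Differential expression reuses the mixed-model ANOVA machinery on log2
expression with a fold-change gate (>= 1.3-fold by default), and cis
effects of promoter methylation on expression are measured by Spearman
rank correlation between a locus's beta and the expression of genes whose
TSS lies within 2 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dml import bh_fdr, fit_all_loci

__all__ = [
    "CnSegment",
    "segment_cn",
    "call_segment",
    "phenotype_cn_association",
    "call_de",
    "cis_correlation",
    "overlap_sets",
]

log = logging.getLogger(__name__)


@dataclass
class CnSegment:
    chromosome: str
    start: int  # marker index, 0-based
    end: int  # half-open
    n_markers: int
    mean_cn: float
    call: str  # amplification / deletion / neutral


def call_segment(mean_cn: float, amp_min: float = 2.5, del_max: float = 1.5) -> str:
    if mean_cn >= amp_min:
        return "amplification"
    if mean_cn <= del_max:
        return "deletion"
    return "neutral"


def _best_split(values: np.ndarray, min_markers: int) -> tuple[int | None, float]:
    """Breakpoint with the smallest two-sample-t p between flanks, or None.

    Pooled-variance t: with a candidate split off the true breakpoint one
    flank mixes both levels, and Welch's per-flank variances would reward
    that asymmetry, mislocalizing the boundary.
    """
    n = values.size
    best_p, best_i = np.inf, None
    for i in range(min_markers, n - min_markers + 1):
        left, right = values[:i], values[i:]
        if np.ptp(left) == 0 and np.ptp(right) == 0:
            if left[0] == right[0]:
                continue  # flat across the split: no evidence at all
            p = 0.0
        else:
            p = stats.ttest_ind(left, right, equal_var=True).pvalue
            if not np.isfinite(p):
                continue
        if p < best_p:
            best_p, best_i = float(p), i
    return best_i, (best_p if best_i is not None else 1.0)


def segment_cn(
    values,
    chromosome: str = "1",
    min_markers: int = 10,
    p_threshold: float = 0.001,
    amp_min: float = 2.5,
    del_max: float = 1.5,
) -> list[CnSegment]:
    """Recursive binary segmentation of one chromosome's ordered CN values."""
    values = np.asarray(values, dtype=float)

    def recurse(lo: int, hi: int) -> list[tuple[int, int]]:
        seg = values[lo:hi]
        if seg.size < 2 * min_markers:
            return [(lo, hi)]
        i, p = _best_split(seg, min_markers)
        if i is None or p >= p_threshold:
            return [(lo, hi)]
        return recurse(lo, lo + i) + recurse(lo + i, hi)

    segments = []
    for lo, hi in recurse(0, values.size):
        mean_cn = float(values[lo:hi].mean())
        segments.append(
            CnSegment(
                chromosome=chromosome, start=lo, end=hi, n_markers=hi - lo,
                mean_cn=mean_cn, call=call_segment(mean_cn, amp_min, del_max),
            )
        )
    return segments


def phenotype_cn_association(calls: pd.DataFrame, phenotype: pd.Series) -> pd.Series:
    """Pearson chi-square p of per-sample segment calls vs phenotype.

    ``calls`` is segments x samples (call strings); ``phenotype`` labels the
    samples.  Zero-margin tables (a call or phenotype level absent) give
    p = 1, flagged in the log.
    """
    if phenotype.nunique() < 2:
        raise ValueError("need at least 2 phenotype groups")
    p_out = {}
    for seg_id, row in calls.iterrows():
        table = pd.crosstab(row.to_numpy(), phenotype.loc[row.index].to_numpy())
        if table.shape[0] < 2 or table.shape[1] < 2:
            log.info("segment %s: single call level, association undefined (p=1)", seg_id)
            p_out[seg_id] = 1.0
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        p_out[seg_id] = float(p)
    return pd.Series(p_out, name="p")


def call_de(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    fold_min: float = 1.3,
    fdr_q: float = 0.05,
    factors: tuple[str, ...] = ("tissue", "sex", "location", "case"),
) -> tuple[frozenset, frozenset, pd.DataFrame]:
    """Differentially expressed genes via the mixed ANOVA on log2 expression.

    Up/down sets require BH q <= ``fdr_q`` and fold = 2^|mean log2
    difference| >= ``fold_min`` with the corresponding sign.  Returns
    (up, down, per-gene table).
    """
    results = fit_all_loci(expression, samples, factors=factors)
    results = results.rename(columns={"delta_beta": "log2_fold"})
    fold = 2.0 ** results["log2_fold"].abs()
    sig = results["q_tissue"] <= fdr_q
    up = frozenset(results.index[sig & (fold >= fold_min) & (results["log2_fold"] > 0)])
    down = frozenset(results.index[sig & (fold >= fold_min) & (results["log2_fold"] < 0)])
    results["fold"] = fold
    return up, down, results


def cis_correlation(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    manifest: pd.DataFrame,
    max_distance: int = 2000,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of locus beta vs expression of genes within 2 kb.

    Gene TSS positions are taken from the manifest (locus position minus its
    annotated TSS distance); a (locus, gene) pair is emitted only when
    |locus position - gene TSS| <= ``max_distance`` and at least
    ``min_samples`` paired samples are available.
    """
    shared = beta.columns.intersection(expression.columns)
    if len(shared) == 0:
        raise ValueError("beta and expression share no sample columns")
    genes = manifest.groupby("gene").agg(
        tss=("position", "first"), chromosome=("chromosome", "first")
    )
    genes["tss"] = (manifest["position"] - manifest["tss_distance"]).groupby(manifest["gene"]).first()
    genes = genes[genes.index.isin(expression.index)]
    beta_sub = beta[shared]
    expr_sub = expression[shared]

    rows = []
    for chrom, gsub in genes.groupby("chromosome"):
        gsub = gsub.sort_values("tss")
        tss = gsub["tss"].to_numpy()
        loci = manifest[(manifest["chromosome"] == chrom) & manifest.index.isin(beta.index)]
        pos = loci["position"].to_numpy()
        lo = np.searchsorted(tss, pos - max_distance, side="left")
        hi = np.searchsorted(tss, pos + max_distance, side="right")
        for (locus, rec), a, b in zip(loci.iterrows(), lo, hi):
            for gi in range(a, b):
                gene = gsub.index[gi]
                x = beta_sub.loc[locus].to_numpy(dtype=float)
                y = expr_sub.loc[gene].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_samples:
                    log.info("pair (%s, %s) skipped: fewer than %d paired samples",
                             locus, gene, min_samples)
                    continue
                rho, p = stats.spearmanr(x[ok], y[ok])
                rows.append(
                    {"locus_id": locus, "gene": gene, "spearman_rho": float(rho),
                     "p": float(p), "distance": int(abs(rec["position"] - tss[gi]))}
                )
    return pd.DataFrame(rows, columns=["locus_id", "gene", "spearman_rho", "p", "distance"])


def overlap_sets(set_a, set_b, set_c, labels: tuple[str, str, str]) -> dict:
    """All seven Venn regions for three gene sets, plus the member lists.

    Region keys are binary membership strings over ``labels`` order, e.g.
    "110" = in the first two sets only.
    """
    A, B, C = (frozenset(s) for s in (set_a, set_b, set_c))
    universe = A | B | C
    regions: dict[str, list] = {}
    for g in sorted(universe):
        key = f"{int(g in A)}{int(g in B)}{int(g in C)}"
        regions.setdefault(key, []).append(g)
    counts = {k: len(v) for k, v in regions.items()}
    return {
        "labels": list(labels),
        "counts": counts,
        "genes": regions,
        "pairwise": {
            f"{labels[0]}&{labels[1]}": sorted(A & B),
            f"{labels[1]}&{labels[2]}": sorted(B & C),
            f"{labels[0]}&{labels[2]}": sorted(A & C),
            "&".join(labels): sorted(A & B & C),
        },
    }
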