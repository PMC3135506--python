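"""Gene-set level analysis of differential methylation.

Three complementary views are implemented:

* chi-square GO enrichment of a significant-gene list against the chip
  background, scored as ES = -log10(p);
* preranked GSEA: a weighted Kolmogorov-Smirnov running sum over the
  ranked gene list, normalized against a gene-label permutation null
  (NES), with a permutation p-value; and
* GO-ANOVA: one mixed model per gene set fitted jointly on every member
  locus, with tissue, gene and patient effects and a random
  sample-within-tissue-by-patient effect, so the category-level tissue
  effect is tested against sample-to-sample variation rather than
  locus-level noise.

Reported sets combine all filters: GSEA permutation p, |NES|, GO-ANOVA
FDR and a mean delta-beta magnitude over member loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import SequentialAnova
from .dml import bh_fdr
from .preprocess import BetaMatrix

__all__ = [
    "GeneSet",
    "go_enrichment",
    "gsea_preranked",
    "gsea_es",
    "go_anova",
    "go_anova_all",
    "select_reported_sets",
    "gene_level_stats",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")
        # symbols are matched case-insensitively throughout
        object.__setattr__(self, "genes", frozenset(str(g).upper() for g in self.genes))


def _upper(genes) -> frozenset:
    return frozenset(str(g).upper() for g in genes)


def go_enrichment(
    sig_genes, manifest_genes, gene_sets: list[GeneSet]
) -> pd.DataFrame:
    """Per-set 2x2 chi-square of significant vs chip gene proportions.

    Compares "significant genes in the category / all significant genes"
    against "chip genes in the category / all chip genes" without
    continuity correction; ES = -log10(p).  Sets with any expected cell
    below 1 are flagged (``low_expected``), not dropped.  Results are
    sorted by ES descending.
    """
    chip = _upper(manifest_genes)
    sig = _upper(sig_genes) & chip
    if not set(_upper(sig_genes)) <= chip:
        raise ValueError("significant genes must be a subset of the chip genes")
    rows = []
    for gs in gene_sets:
        members = gs.genes & chip
        a = len(sig & members)  # significant, in set
        b = len(sig) - a  # significant, outside
        c = len(members) - a  # not significant, in set
        d = len(chip) - len(sig) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        if not sig:
            chi2, p = 0.0, 1.0
        elif table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = 0.0, 1.0  # degenerate margins carry no signal
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        expected_min = (
            np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        ).min() if table.sum() else 0.0
        rows.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "sig_in_set": a,
                "sig_total": len(sig),
                "chip_in_set": len(members),
                "chip_total": len(chip),
                "chi_square": float(chi2),
                "p": float(p),
                "enrichment_score": float(-np.log10(max(p, 1e-300))) if p < 1 else 0.0,
                "low_expected": bool(expected_min < 1),
            }
        )
    if not sig:
        log.warning("empty significant-gene list: all enrichment scores are 0")
    out = pd.DataFrame(rows).set_index("set_id")
    return out.sort_values("enrichment_score", ascending=False)


def gsea_es(stat_sorted: np.ndarray, hit_positions: np.ndarray, weight_exponent: float = 1.0) -> float:
    """Enrichment score of one set on a descending-ranked statistic vector.

    Hit increments are proportional to |stat|^weight_exponent, miss
    decrements are 1/(N - |S|); the ES is the running-sum extreme of
    largest magnitude (signed).
    """
    N = stat_sorted.size
    m = hit_positions.size
    pos = np.sort(hit_positions)
    w = np.abs(stat_sorted[pos]) ** weight_exponent
    total = w.sum()
    cumw = np.cumsum(w) / total if total > 0 else (np.arange(1, m + 1) / m)
    miss = 1.0 / (N - m)
    after = cumw - (pos - np.arange(m)) * miss  # running sum just after each hit
    before = after - np.diff(np.r_[0.0, cumw])  # just before each hit
    hi = after.max()
    lo = min(before.min(), 0.0)
    # magnitude ties (up to rounding) resolve to the positive extreme
    return float(hi if hi >= -lo - 1e-12 else lo)


def _perm_es(
    stat_sorted: np.ndarray, m: int, n_perm: int, weight_exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets (label permutation)."""
    N = stat_sorted.size
    idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :m]
    idx.sort(axis=1)
    w = np.abs(stat_sorted[idx]) ** weight_exponent
    total = w.sum(axis=1, keepdims=True)
    safe = np.where(total > 0, total, 1.0)
    cumw = np.cumsum(w, axis=1) / safe
    miss = 1.0 / (N - m)
    offsets = np.arange(m)[None, :]
    after = cumw - (idx - offsets) * miss
    before = after - w / safe
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo - 1e-12, hi, lo)


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked_stats`` maps gene -> signed statistic (any order; ranked here).
    NES = ES / mean(|ES*|) over the same-sign permutation scores; the
    permutation p is (1 + #{|ES*| >= |ES|, same sign}) / (1 + #same sign).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    stats_ = ranked_stats.copy()
    stats_.index = stats_.index.str.upper()
    order = np.argsort(-stats_.to_numpy(), kind="stable")
    genes = stats_.index.to_numpy()[order]
    stat_sorted = stats_.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(genes)}

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gs in gene_sets:
        pos = np.array(sorted(gene_pos[g] for g in gs.genes if g in gene_pos))
        if pos.size < min_set_size:
            log.info("set %s skipped: only %d ranked members", gs.set_id, pos.size)
            continue
        es = gsea_es(stat_sorted, pos, weight_exponent)
        m = pos.size
        if m not in null_cache:
            null_cache[m] = _perm_es(stat_sorted, m, n_perm, weight_exponent, rng)
        null = null_cache[m]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            nes, p = 0.0, 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same).mean()
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
        rows.append(
            {"set_id": gs.set_id, "name": gs.name, "size": m, "es": es, "nes": float(nes),
             "p": float(p), "n_permutations": n_perm}
        )
    return pd.DataFrame(rows).set_index("set_id")


def gene_level_stats(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Collapse per-locus statistics to genes for preranked GSEA.

    The ranking statistic is signed significance, ``-log10(p_tissue) *
    sign(delta_beta)``, collapsed per gene by the locus of largest
    magnitude.
    """
    stat = -np.log10(np.maximum(results["p_tissue"].to_numpy(), 1e-300)) * np.sign(
        results["delta_beta"].to_numpy()
    )
    df = pd.DataFrame({"gene": manifest.loc[results.index, "gene"].str.upper(), "stat": stat})
    idx = df.groupby("gene")["stat"].apply(lambda s: s.iloc[np.argmax(np.abs(s.to_numpy()))])
    return idx


def go_anova(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    gene_set: GeneSet,
    manifest: pd.DataFrame,
) -> dict:
    """Category-level mixed ANOVA on all member loci of one gene set.

    The long-format response stacks beta of every member locus over every
    sample; tissue, gene and patient are fixed effects and the
    sample-within-tissue-by-patient effect is random, so the tissue F is
    tested against the sample stratum.  Returns the tissue p and the
    unweighted mean delta beta over member loci.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    member_loci = manifest.index[manifest["gene"].str.upper().isin(gene_set.genes)]
    member_loci = member_loci.intersection(values.index)
    if len(member_loci) == 0:
        raise ValueError(f"gene set {gene_set.set_id} has no loci with data")
    sub = values.loc[member_loci]
    is_tumor = (samples.loc[sub.columns, "tissue"] == "tumor").to_numpy()
    per_locus_delta = sub.to_numpy()[:, is_tumor].mean(axis=1) - sub.to_numpy()[:, ~is_tumor].mean(axis=1)
    mean_delta = float(per_locus_delta.mean())

    if len(member_loci) == 1:
        from .dml import fit_locus_mixed_anova

        res = fit_locus_mixed_anova(sub.iloc[0].to_numpy(), samples.loc[sub.columns])
        return {"set_id": gene_set.set_id, "p": res.p["tissue"], "mean_delta_beta": mean_delta,
                "n_loci": 1, "single_locus_fallback": True}

    n_loci, n_samples = sub.shape
    long_y = sub.to_numpy().reshape(1, -1)  # locus-major: obs = (locus, sample)
    obs = pd.DataFrame(
        {
            "tissue": np.tile(samples.loc[sub.columns, "tissue"].to_numpy(), n_loci),
            "gene": np.repeat(manifest.loc[member_loci, "gene"].to_numpy(), n_samples),
            "case_id": np.tile(samples.loc[sub.columns, "case_id"].to_numpy(), n_loci),
            "sample_id": np.tile(sub.columns.to_numpy(), n_loci),
        }
    )
    seq = SequentialAnova.from_samples(obs, ("tissue", "gene", "patient", "sample"))
    ss = seq.decompose(long_y)
    tests = seq.f_tests(ss, {"tissue": "sample", "patient": "sample", "gene": "residual"})
    return {
        "set_id": gene_set.set_id,
        "p": float(tests["tissue"][1][0]),
        "mean_delta_beta": mean_delta,
        "n_loci": int(n_loci),
        "single_locus_fallback": False,
    }


def go_anova_all(
    beta: BetaMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    gene_sets: list[GeneSet],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """GO-ANOVA for every set, with BH FDR across sets."""
    rows = []
    for gs in gene_sets:
        try:
            rows.append(go_anova(beta, samples, gs, manifest))
        except ValueError:
            log.info("set %s skipped in GO-ANOVA: no loci with data", gs.set_id)
    out = pd.DataFrame(rows).set_index("set_id")
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out


def select_reported_sets(
    gsea_results: pd.DataFrame,
    goanova_results: pd.DataFrame,
    nes_cut: float = 1.5,
    es_p: float = 0.01,
    goanova_fdr: float = 0.01,
    mean_db: float = 0.1,
) -> pd.DataFrame:
    """Sets passing all four filters, sorted by NES descending."""
    joined = gsea_results.join(goanova_results[["p", "fdr_q", "mean_delta_beta"]],
                               rsuffix="_goanova", how="inner")
    keep = (
        (joined["p"] <= es_p)
        & (joined["nes"].abs() >= nes_cut)
        & (joined["fdr_q"] <= goanova_fdr)
        & (joined["mean_delta_beta"].abs() >= mean_db)
    )
    return joined[keep].sort_values("nes", ascending=False)
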