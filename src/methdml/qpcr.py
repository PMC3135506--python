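"""Methylated-fraction quantification from restriction-digest qPCR.

The assay digests the same DNA four ways — mock (Mo), methyl-sensitive
enzyme (Ms, cuts unmethylated copies), methyl-dependent enzyme (Md, cuts
methylated copies) and both (Msd) — and reads a qPCR Ct per digest.  The
fraction of template surviving a digest follows the delta-delta-Ct rule
``2^-(ct_digest - ct_mock)``: survival of the Ms digest estimates the
hypermethylated fraction, survival of the Md digest the unmethylated
fraction, and the double digest measures refractory background.  The
intermediate fraction is the remainder; the triple is clipped to [0, 1]
and renormalized to sum to one.  A Ct at the maximum cycle means no
amplification, i.e. a surviving fraction of exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MAX_CYCLE

__all__ = ["CtQuadruple", "MethylFractions", "quantify_fractions", "quantify_table", "platform_concordance"]

log = logging.getLogger(__name__)


@dataclass
class CtQuadruple:
    gene: str
    sample: str
    ct_mock: float
    ct_ms: float
    ct_md: float
    ct_msd: float
    max_cycle: float = MAX_CYCLE

    def __post_init__(self) -> None:
        for name in ("ct_ms", "ct_md", "ct_msd"):
            if getattr(self, name) < self.ct_mock - 0.5:
                raise ValueError(f"{name} below ct_mock - 0.5: digestion cannot add template")


@dataclass
class MethylFractions:
    gene: str
    sample: str
    f_um: float
    f_im: float
    f_hm: float
    inconsistent: bool = False

    @property
    def methylated_total(self) -> float:
        return self.f_im + self.f_hm


def _survival(ct: float, ct_mock: float, max_cycle: float) -> float:
    if ct >= max_cycle:
        return 0.0
    return float(2.0 ** (-(ct - ct_mock)))


def quantify_fractions(quad: CtQuadruple) -> MethylFractions:
    """Recover (unmethylated, intermediate, hypermethylated) fractions.

    Only Ct differences enter, so the result is invariant to a constant
    shift of all four Ct values.  Records where the two single digests
    account for more than 110% of the template before correction are
    flagged as assay-inconsistent (and still renormalized).
    """
    f_hm = _survival(quad.ct_ms, quad.ct_mock, quad.max_cycle)
    f_um = _survival(quad.ct_md, quad.ct_mock, quad.max_cycle)
    background = _survival(quad.ct_msd, quad.ct_mock, quad.max_cycle)
    inconsistent = f_hm + f_um > 1.1
    if inconsistent:
        log.warning("assay-inconsistent record %s/%s: f_hm + f_um = %.3f",
                    quad.gene, quad.sample, f_hm + f_um)
    f_im = max(0.0, 1.0 - f_hm - f_um - background)
    f_hm = min(max(f_hm, 0.0), 1.0)
    f_um = min(max(f_um, 0.0), 1.0)
    total = f_um + f_im + f_hm
    if total > 0:
        f_um, f_im, f_hm = f_um / total, f_im / total, f_hm / total
    return MethylFractions(quad.gene, quad.sample, f_um=f_um, f_im=f_im, f_hm=f_hm,
                           inconsistent=inconsistent)


def quantify_table(ct_table: pd.DataFrame, max_cycle: float = MAX_CYCLE) -> pd.DataFrame:
    """Quantify a long-format Ct table (gene, sample, digest, ct).

    Digest labels are Mo / Ms / Md / Msd; returns one row per (gene, sample)
    with the fraction triple and the methylated total f_im + f_hm.
    """
    wide = ct_table.pivot_table(index=["gene", "sample"], columns="digest", values="ct")
    missing = {"Mo", "Ms", "Md", "Msd"} - set(wide.columns)
    if missing:
        raise ValueError(f"Ct table lacks digests: {sorted(missing)}")
    rows = []
    for (gene, sample), rec in wide.iterrows():
        quad = CtQuadruple(gene, sample, ct_mock=rec["Mo"], ct_ms=rec["Ms"],
                           ct_md=rec["Md"], ct_msd=rec["Msd"], max_cycle=max_cycle)
        fr = quantify_fractions(quad)
        rows.append({"gene": gene, "sample": sample, "f_um": fr.f_um, "f_im": fr.f_im,
                     "f_hm": fr.f_hm, "methylated_total": fr.methylated_total,
                     "inconsistent": fr.inconsistent})
    return pd.DataFrame(rows)


def platform_concordance(
    fractions: pd.DataFrame,
    beta: pd.DataFrame,
    gene_to_locus: pd.Series,
    samples: pd.DataFrame | None = None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Per-gene Pearson r between qPCR methylated total and array beta.

    ``gene_to_locus`` maps each assayed gene to its array locus.  When a
    sample table is supplied, the per-gene mean tumor - normal difference is
    reported on both platforms along with sign agreement.
    """
    rows = []
    for gene, sub in fractions.groupby("gene"):
        locus = gene_to_locus[gene]
        sub = sub[sub["sample"].isin(beta.columns)]
        if len(sub) < min_pairs:
            raise ValueError(f"gene {gene}: fewer than {min_pairs} paired observations")
        q = sub.set_index("sample")["methylated_total"]
        b = beta.loc[locus, q.index].astype(float)
        if q.nunique() <= 1 or b.nunique() <= 1:
            log.warning("gene %s: constant vector, correlation undefined", gene)
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(q.to_numpy(), b.to_numpy())
        row = {"gene": gene, "locus_id": locus, "n": len(q), "r": float(r), "p": float(p)}
        if samples is not None:
            tissue = samples.loc[q.index, "tissue"]
            dq = q[tissue == "tumor"].mean() - q[tissue == "normal"].mean()
            db = b[tissue == "tumor"].mean() - b[tissue == "normal"].mean()
            row.update(
                qpcr_diff=float(dq), array_diff=float(db),
                sign_agreement=bool(np.sign(dq) == np.sign(db)),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
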