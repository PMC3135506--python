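"""Synthetic paired tumor/normal methylation studies with planted truth.

Emulates a promoter-focused two-channel methylation chip read on paired
tumor and adjacent-normal tissue from the same cases, together with the
coupled data types used downstream: an expression matrix cis-coupled to
promoter methylation, a per-marker copy-number table with planted
amplifications/deletions, and restriction-digest qPCR Ct quadruples
consistent with known methylated fractions.  Every planted effect is
recorded in a :class:`TruthTable`, so recovery can be scored exactly.

Study-scale defaults mirror the emulated design: 24 cases x 2 tissues run
as 12 samples/chip, ~27.5K promoter CpG loci over ~14.5K genes (about 1.9
loci per gene), TSS distances 0-1499 bp, and a small excess of
X-chromosome loci whose female samples drift toward hemimethylation
(X-inactivation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Manifest",
    "IntensityStudy",
    "TruthTable",
    "generate_manifest",
    "generate_sample_table",
    "generate_paired_study",
    "generate_multiomics",
    "generate_qpcr",
    "fractions_from_beta",
    "default_dml_plan",
]

# Conventions for the emulated chip; the real instrument's intensity
# distributions are unpublished, only relative magnitudes matter here.
MAX_CYCLE = 40.0
_NEG_CONTROL_RATIO = 20.0
_LOGNORM_SIGMA = 0.3
AUTOSOMES = tuple(str(i) for i in range(1, 23))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


Manifest = pd.DataFrame  # index locus_id; columns gene, chromosome, position, tss_distance, go_terms


@dataclass
class IntensityStudy:
    """Two-channel intensities plus negative controls and sample metadata."""

    M: pd.DataFrame  # loci x samples, methylated-probe signal
    U: pd.DataFrame  # loci x samples, unmethylated-probe signal
    negatives: pd.DataFrame  # negative-control beads x samples
    samples: pd.DataFrame  # index sample_id; case_id, tissue, sex, location, chip_id
    manifest: Manifest

    def __post_init__(self) -> None:
        if self.M.shape != self.U.shape:
            raise ValueError("M and U must have identical shape")
        missing = set(self.samples.index) - set(self.M.columns)
        if missing:
            raise ValueError(f"samples without intensity columns: {sorted(missing)}")


@dataclass
class TruthTable:
    """Exactly what was simulated, keyed the same way as the outputs."""

    loci: pd.DataFrame  # index locus_id; delta_beta, sex_effect, affected_by
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)  # log2_fold, cis_coupled
    cn_regions: pd.DataFrame = field(default_factory=pd.DataFrame)  # chrom, start/end marker, cn
    metadata: dict = field(default_factory=dict)

    def affected(self, factor: str) -> pd.Index:
        mask = self.loci["affected_by"].map(lambda s: factor in s)
        return self.loci.index[mask]


def generate_manifest(
    n_loci: int = 27578,
    n_genes: int = 14495,
    frac_x: float = 1085 / 27578,
    frac_y: float = 7 / 27578,
    n_go_terms: int | None = None,
    seed: int = 0,
) -> Manifest:
    """Random chip manifest: loci assigned to genes, chromosomes and GO terms.

    Exactly ``round(frac_x * n_loci)`` loci land on X and ``round(frac_y *
    n_loci)`` on Y (half-up rounding); every gene receives at least one
    locus; TSS distances are uniform on [0, 1499] bp.
    """
    if not (isinstance(n_loci, (int, np.integer)) and isinstance(n_genes, (int, np.integer))):
        raise ValueError("n_loci and n_genes must be integers")
    if n_loci < n_genes or n_genes < 1:
        raise ValueError("require n_loci >= n_genes >= 1")
    if not (0 <= frac_x <= 1 and 0 <= frac_y <= 1 and frac_x + frac_y < 1):
        raise ValueError("chromosome fractions must lie in [0,1] with frac_x+frac_y < 1")
    if n_go_terms is None:
        # ~25 genes per annotation term on average, like focused GO leaf terms
        n_go_terms = max(20, n_genes // 25)
    rng = np.random.default_rng(seed)

    # every gene gets one locus, the surplus is spread at random
    gene_ids = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    gene_of_locus = np.concatenate(
        [np.arange(n_genes), rng.integers(0, n_genes, size=n_loci - n_genes)]
    )
    rng.shuffle(gene_of_locus)
    loci_per_gene = np.bincount(gene_of_locus, minlength=n_genes)

    n_x = _round_half_up(frac_x * n_loci)
    n_y = _round_half_up(frac_y * n_loci)
    # fill the sex chromosomes gene-by-gene so each gene stays on one chromosome
    gene_chrom = rng.choice(AUTOSOMES, size=n_genes)
    order = rng.permutation(n_genes)
    for chrom, target in (("X", n_x), ("Y", n_y)):
        remaining = target
        for g in order:
            if remaining == 0:
                break
            if gene_chrom[g] in ("X", "Y"):
                continue
            if loci_per_gene[g] <= remaining:
                gene_chrom[g] = chrom
                remaining -= int(loci_per_gene[g])
        if remaining:
            raise ValueError("could not satisfy sex-chromosome locus counts exactly")

    # one promoter (TSS anchor) per gene; loci sit 0-1499 bp from it
    gene_tss = rng.integers(10_000, 200_000_000, size=n_genes)
    tss_distance = rng.integers(0, 1500, size=n_loci)
    position = gene_tss[gene_of_locus] + tss_distance

    go_pool = np.array([f"GO:{i:07d}" for i in range(n_go_terms)])
    gene_terms = [
        ";".join(sorted(rng.choice(go_pool, size=rng.integers(1, 4), replace=False)))
        for _ in range(n_genes)
    ]

    manifest = pd.DataFrame(
        {
            "gene": gene_ids[gene_of_locus],
            "chromosome": gene_chrom[gene_of_locus],
            "position": position,
            "tss_distance": tss_distance,
            "go_terms": [gene_terms[g] for g in gene_of_locus],
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n_loci)], name="locus_id"),
    )
    return manifest


def generate_sample_table(n_cases: int = 24, female_frac: float = 7 / 24, seed: int = 0) -> pd.DataFrame:
    """Paired sample sheet: one tumor and one normal per case, 12 samples/chip."""
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    rng = np.random.default_rng(seed)
    n_f = min(max(_round_half_up(female_frac * n_cases), 1), n_cases - 1)
    sexes = np.array(["F"] * n_f + ["M"] * (n_cases - n_f))
    rng.shuffle(sexes)
    locations = rng.choice(["proximal", "distal"], size=n_cases)
    rows = []
    for i in range(n_cases):
        case = f"case{i + 1:02d}"
        chip = f"chip{i // 6 + 1}"  # 6 cases = 12 samples per chip
        for tissue in ("tumor", "normal"):
            rows.append(
                {
                    "sample_id": f"{case}_{tissue}",
                    "case_id": case,
                    "tissue": tissue,
                    "sex": sexes[i],
                    "location": locations[i],
                    "chip_id": chip,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def default_dml_plan(
    manifest: Manifest,
    n_hyper: int = 350,
    n_hypo: int = 150,
    delta: float = 0.35,
    seed: int = 0,
) -> list[tuple[Sequence[str], float]]:
    """Pick autosomal loci for planting: a hyper set (+delta) and a hypo set (-delta)."""
    rng = np.random.default_rng(seed)
    autosomal = manifest.index[~manifest["chromosome"].isin(["X", "Y"])]
    chosen = rng.choice(autosomal, size=n_hyper + n_hypo, replace=False)
    return [(list(chosen[:n_hyper]), delta), (list(chosen[n_hyper:]), -delta)]


def go_biased_dml_plan(
    manifest: Manifest,
    n_hyper: int = 350,
    n_hypo: int = 150,
    delta: float = 0.35,
    n_enriched_terms: int = 2,
    enriched_frac: float = 0.6,
    seed: int = 0,
) -> list[tuple[Sequence[str], float]]:
    """Planting plan where part of the hyper set concentrates in a few GO terms.

    Tumor hypermethylation tends to hit coordinated pathways; concentrating
    ``enriched_frac`` of the hypermethylated loci in ``n_enriched_terms``
    randomly chosen GO categories gives the gene-set analyses a real signal
    to find.  The remainder (and the hypo set) is drawn uniformly from
    autosomal loci as in :func:`default_dml_plan`.
    """
    rng = np.random.default_rng(seed)
    autosomal = manifest[~manifest["chromosome"].isin(["X", "Y"])]
    terms = sorted({t for s in autosomal["go_terms"] for t in str(s).split(";") if t})
    chosen_terms = set(rng.choice(terms, size=min(n_enriched_terms, len(terms)), replace=False))
    in_terms = autosomal.index[
        autosomal["go_terms"].map(lambda s: bool(chosen_terms & set(str(s).split(";"))))
    ]
    n_concentrated = min(int(round(enriched_frac * n_hyper)), len(in_terms))
    hyper = list(rng.choice(in_terms, size=n_concentrated, replace=False))
    rest = autosomal.index.difference(hyper)
    fill = rng.choice(rest, size=n_hyper - n_concentrated + n_hypo, replace=False)
    hyper += list(fill[: n_hyper - n_concentrated])
    hypo = list(fill[n_hyper - n_concentrated:])
    return [(hyper, delta), (hypo, -delta)]


def generate_paired_study(
    manifest: Manifest,
    n_cases: int = 24,
    dml_plan: Sequence[tuple[Sequence[str], float]] = (),
    sex_effect_x: float = 0.2,
    subject_sd: float = 0.02,
    noise_sd: float = 0.03,
    total_intensity_mean: float = 5000.0,
    n_negative_controls: int = 32,
    seed: int = 0,
) -> tuple[IntensityStudy, TruthTable]:
    """Simulate paired two-channel intensities with planted effects.

    Latent methylation per locus and sample is ``clip(baseline + tissue
    effect + sex effect + subject effect + noise, 0, 1)``; the channel pair
    is then ``M = round(T * beta)``, ``U = T - M`` with total intensity ``T``
    lognormal around ``total_intensity_mean``.  Baselines are drawn from a
    bimodal mixture (mostly-unmethylated / mostly-methylated promoters) kept
    away from the [0,1] edges so additive noise is rarely clipped.

    The sex effect shifts X-chromosome loci of female samples toward 0.5
    (hemimethylation under X-inactivation).  Subject effects are shared by
    the tumor/normal pair of a case.
    """
    if subject_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    for loci, _ in dml_plan:
        unknown = set(loci) - set(manifest.index)
        if unknown:
            raise ValueError(f"planted loci not in manifest: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    samples = generate_sample_table(n_cases, seed=rng.integers(2**31))
    n_loci, n_samples = len(manifest), len(samples)

    # flat baseline across the unit interval: keeps every quantile populated,
    # so rank-based normalization stays comparable across routes and additive
    # noise is almost never clipped (real chips are bimodal; see docs)
    baseline = rng.uniform(0.05, 0.95, size=n_loci)

    tissue_effect = np.zeros(n_loci)
    locus_pos = pd.Series(np.arange(n_loci), index=manifest.index)
    for loci, delta in dml_plan:
        idx = locus_pos[list(loci)].to_numpy()
        tissue_effect[idx] += delta
        # hypermethylation is planted on unmethylated promoters and vice
        # versa: keep the shifted level inside [0.05, 0.95] so the effect
        # survives clipping at full size
        lo, hi = (0.05, 0.95 - delta) if delta > 0 else (0.05 - delta, 0.95)
        baseline[idx] = np.clip(baseline[idx], lo, hi)

    is_x = (manifest["chromosome"] == "X").to_numpy()
    sex_shift = np.where(baseline < 0.5, sex_effect_x, -sex_effect_x) * is_x

    is_tumor = (samples["tissue"] == "tumor").to_numpy()
    is_female = (samples["sex"] == "F").to_numpy()
    case_codes = pd.Categorical(samples["case_id"]).codes

    subject = rng.normal(0.0, subject_sd, size=(n_loci, n_cases))[:, case_codes] if subject_sd else 0.0
    noise = rng.normal(0.0, noise_sd, size=(n_loci, n_samples)) if noise_sd else 0.0
    latent = (
        baseline[:, None]
        + np.outer(tissue_effect, is_tumor)
        + np.outer(sex_shift, is_female)
        + subject
        + noise
    )
    beta = np.clip(latent, 0.0, 1.0)
    clipped_frac = float(np.mean((latent < 0) | (latent > 1)))

    sigma = _LOGNORM_SIGMA
    mu = np.log(total_intensity_mean) - sigma**2 / 2
    T = np.rint(rng.lognormal(mu, sigma, size=(n_loci, n_samples)))
    M = np.rint(T * beta)
    U = T - M

    neg_mu = np.log(total_intensity_mean / _NEG_CONTROL_RATIO) - sigma**2 / 2
    negatives = rng.lognormal(neg_mu, sigma, size=(n_negative_controls, n_samples))

    cols = samples.index
    study = IntensityStudy(
        M=pd.DataFrame(M, index=manifest.index, columns=cols),
        U=pd.DataFrame(U, index=manifest.index, columns=cols),
        negatives=pd.DataFrame(negatives, columns=cols),
        samples=samples,
        manifest=manifest,
    )

    affected = [set() for _ in range(n_loci)]
    for i in np.flatnonzero(tissue_effect != 0):
        affected[i].add("tissue")
    for i in np.flatnonzero(is_x & (np.abs(sex_shift) > 0)):
        affected[i].add("sex")
    truth_loci = pd.DataFrame(
        {
            "delta_beta": tissue_effect,
            "sex_effect": sex_shift,
            "affected_by": [frozenset(a) for a in affected],
        },
        index=manifest.index,
    )
    metadata = {"seed": int(seed), "clipped_fraction": clipped_frac}
    if clipped_frac > 0.01:
        msg = f"{clipped_frac:.2%} of latent beta draws clipped to [0,1]"
        metadata["clip_warning"] = msg
        warnings.warn(msg, stacklevel=2)
    return study, TruthTable(loci=truth_loci, metadata=metadata)


def generate_multiomics(
    truth: TruthTable,
    manifest: Manifest,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    coupling_rho: float = -0.8,
    n_coupled_genes: int = 50,
    cn_plan: Sequence[tuple[str, int, int, float]] = (),
    de_plan: Sequence[tuple[Sequence[str], float]] = (),
    n_markers_per_chrom: int = 200,
    expr_noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Expression matrix and per-marker CN table coupled to the methylation study.

    Cis-coupled genes get log2 expression built through a Gaussian copula
    against the gene's promoter beta, targeting Spearman ``coupling_rho``
    across samples.  CN regions in ``cn_plan`` (chromosome, first marker,
    last marker inclusive, copy number) shift marker values for tumor
    samples and add a ``log2(cn/2)`` dosage term to the expression of genes
    inside the region.  ``de_plan`` plants plain tumor/normal expression
    fold changes (gene list, log2 fold).
    """
    if not -1 <= coupling_rho <= 1:
        raise ValueError("coupling_rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = manifest["gene"].unique()
    n_genes, n_samples = len(genes), len(samples)
    is_tumor = (samples["tissue"] == "tumor").to_numpy()

    base = rng.normal(8.0, 1.5, size=n_genes)
    expr = base[:, None] + rng.normal(0.0, expr_noise_sd, size=(n_genes, n_samples))
    expr = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples.index)

    # promoter beta per gene = beta of the gene's locus closest to the TSS
    rep_locus = (
        manifest.sort_values("tss_distance").reset_index().drop_duplicates("gene").set_index("gene")["locus_id"]
    )
    coupled = rng.choice(genes, size=min(n_coupled_genes, n_genes), replace=False)
    rho_p = 2 * np.sin(np.pi * coupling_rho / 6)  # Pearson target giving Spearman rho
    from scipy.stats import norm, rankdata

    for g in coupled:
        b = beta.loc[rep_locus[g]].to_numpy(dtype=float)
        z = norm.ppf((rankdata(b) - 0.5) / n_samples)
        e = rho_p * z + np.sqrt(max(0.0, 1 - rho_p**2)) * rng.normal(size=n_samples)
        expr.loc[g] = base[np.flatnonzero(genes == g)[0]] + e  # unit-variance copula scale

    for gene_list, log2_fold in de_plan:
        expr.loc[list(gene_list), samples.index[is_tumor]] += log2_fold

    # CN markers: tumors deviate in planted regions, everything else diploid
    marker_rows = []
    chroms = sorted(manifest["chromosome"].unique(), key=lambda c: (len(c), c))
    for chrom in chroms:
        sub = manifest[manifest["chromosome"] == chrom]
        lo, hi = int(sub["position"].min()), int(sub["position"].max())
        positions = np.linspace(lo, hi, n_markers_per_chrom).astype(int)
        for j, p in enumerate(positions):
            marker_rows.append({"chromosome": chrom, "marker_index": j, "position": int(p)})
    markers = pd.DataFrame(marker_rows)
    cn = 2.0 + rng.normal(0.0, 0.05, size=(len(markers), n_samples))
    region_records = []
    for chrom, start, end, value in cn_plan:
        sel = (markers["chromosome"] == chrom) & markers["marker_index"].between(start, end)
        if not sel.any():
            raise ValueError(f"CN region {chrom}:{start}-{end} outside marker range")
        if end - start + 1 < 10:
            raise ValueError("CN regions must span at least 10 markers")
        cn[np.ix_(sel.to_numpy(), is_tumor)] += value - 2.0
        region_records.append({"chromosome": chrom, "start": start, "end": end, "cn": value})
        # dosage effect on expression of genes inside the region
        pos_lo = markers.loc[sel, "position"].min()
        pos_hi = markers.loc[sel, "position"].max()
        in_region = manifest[
            (manifest["chromosome"] == chrom) & manifest["position"].between(pos_lo, pos_hi)
        ]["gene"].unique()
        expr.loc[expr.index.intersection(in_region), samples.index[is_tumor]] += np.log2(value / 2.0)

    cn_table = pd.concat(
        [markers, pd.DataFrame(cn, columns=samples.index)], axis=1
    )

    gene_truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gene_truth["cis_coupled"] = gene_truth.index.isin(coupled)
    gene_truth["log2_fold"] = 0.0
    for gene_list, log2_fold in de_plan:
        gene_truth.loc[list(gene_list), "log2_fold"] += log2_fold
    updated = TruthTable(
        loci=truth.loci,
        genes=gene_truth,
        cn_regions=pd.DataFrame(region_records),
        metadata=dict(truth.metadata),
    )
    return expr, cn_table, updated


def fractions_from_beta(
    beta: pd.DataFrame, genes: Iterable[str], manifest: Manifest, samples: Iterable[str]
) -> pd.DataFrame:
    """Methylated-fraction triples whose total equals the gene's promoter beta.

    The split ``f_hm = beta^2, f_im = beta(1-beta), f_um = 1-beta`` keeps
    ``f_im + f_hm`` exactly equal to beta, so array/qPCR concordance is
    perfect in the noise-free limit.
    """
    rep_locus = (
        manifest.sort_values("tss_distance").reset_index().drop_duplicates("gene").set_index("gene")["locus_id"]
    )
    rows = []
    for g in genes:
        for s in samples:
            b = float(beta.at[rep_locus[g], s])
            rows.append(
                {"gene": g, "sample": s, "f_um": 1 - b, "f_im": b * (1 - b), "f_hm": b * b}
            )
    return pd.DataFrame(rows)


def generate_qpcr(
    true_fractions: pd.DataFrame,
    ct_mock_mean: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_cycle: float = MAX_CYCLE,
) -> pd.DataFrame:
    """Ct quadruples (Mo, Ms, Md, Msd) for given (f_um, f_im, f_hm) triples.

    Template surviving the methyl-sensitive digest is the hypermethylated
    fraction, template surviving the methyl-dependent digest is the
    unmethylated fraction, and the double digest leaves nothing, so each
    digest Ct is ``ct_mock - log2(surviving fraction)``; a zero fraction
    means no amplification and is reported at ``max_cycle``.
    """
    frac = true_fractions[["f_um", "f_im", "f_hm"]].to_numpy(dtype=float)
    if (frac < 0).any() or not np.allclose(frac.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("fractions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for (_, rec), (f_um, _f_im, f_hm) in zip(true_fractions.iterrows(), frac):
        ct_mock = ct_mock_mean + (rng.normal(0, noise_sd) if noise_sd else 0.0)

        def digest_ct(surviving: float) -> float:
            if surviving <= 0:
                return max_cycle
            ct = ct_mock - np.log2(surviving)
            if noise_sd:
                ct += rng.normal(0, noise_sd)
            return min(ct, max_cycle)

        for digest, ct in (
            ("Mo", ct_mock),
            ("Ms", digest_ct(f_hm)),
            ("Md", digest_ct(f_um)),
            ("Msd", max_cycle),
        ):
            rows.append({"gene": rec["gene"], "sample": rec["sample"], "digest": digest, "ct": ct})
    return pd.DataFrame(rows)
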