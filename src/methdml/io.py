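"""Plain-text readers and writers for every pipeline interchange format.

Everything is TSV/CSV/GMT/JSON so intermediates stay diffable: manifest
and sample sheet as CSV, intensities as TSV with paired ``<sample>.M`` /
``<sample>.U`` columns plus a separate negative-control TSV, beta and
expression matrices as TSV, gene sets in the standard GMT tab format,
qPCR Ct tables as long CSV, and truth/call sets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dml import DMLCall
from .genesets import GeneSet
from .preprocess import BetaMatrix
from .synthetic import IntensityStudy, TruthTable

__all__ = [
    "write_manifest", "read_manifest",
    "write_sample_sheet", "read_sample_sheet",
    "write_intensities", "read_intensities",
    "write_beta", "read_beta",
    "write_matrix", "read_matrix",
    "write_qpcr", "read_qpcr",
    "read_gmt", "write_gmt",
    "write_truth", "read_truth",
    "write_dml_call", "read_dml_call",
]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="locus_id", dtype={"chromosome": str})
    df["go_terms"] = df["go_terms"].fillna("")
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_intensities(study: IntensityStudy, intensity_path, negatives_path) -> None:
    wide = pd.DataFrame(index=study.M.index)
    for s in study.samples.index:
        wide[f"{s}.M"] = study.M[s]
        wide[f"{s}.U"] = study.U[s]
    wide.to_csv(intensity_path, sep="\t")
    study.negatives.to_csv(negatives_path, sep="\t", index=False)


def read_intensities(intensity_path, negatives_path, samples: pd.DataFrame,
                     manifest: pd.DataFrame) -> IntensityStudy:
    wide = pd.read_csv(intensity_path, sep="\t", index_col=0)
    M = pd.DataFrame({s: wide[f"{s}.M"] for s in samples.index})
    U = pd.DataFrame({s: wide[f"{s}.U"] for s in samples.index})
    negatives = pd.read_csv(negatives_path, sep="\t")
    return IntensityStudy(M=M, U=U, negatives=negatives, samples=samples, manifest=manifest)


def write_beta(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t")


def read_beta(path, route: str = "raw") -> BetaMatrix:
    return BetaMatrix(pd.read_csv(path, sep="\t", index_col=0), route=route)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_qpcr(ct_table: pd.DataFrame, path) -> None:
    ct_table.to_csv(path, index=False)


def read_qpcr(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(set_id=parts[0], name=parts[1], genes=frozenset(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    lines = ["\t".join([s.set_id, s.name, *sorted(s.genes)]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: TruthTable, path) -> None:
    payload = {
        "loci": {
            locus: {"delta_beta": float(rec["delta_beta"]),
                    "sex_effect": float(rec["sex_effect"]),
                    "affected_by": sorted(rec["affected_by"])}
            for locus, rec in truth.loci.iterrows()
            if rec["affected_by"]
        },
        "genes": truth.genes.reset_index().to_dict(orient="records") if len(truth.genes) else [],
        "cn_regions": truth.cn_regions.to_dict(orient="records") if len(truth.cn_regions) else [],
        "metadata": truth.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_dml_call(call: DMLCall, path) -> None:
    payload = {
        "route": call.route,
        "delta_beta_min": call.delta_beta_min,
        "fdr_q": call.fdr_q,
        "hyper": sorted(call.hyper),
        "hypo": sorted(call.hypo),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_dml_call(path) -> DMLCall:
    d = json.loads(Path(path).read_text())
    return DMLCall(hyper=frozenset(d["hyper"]), hypo=frozenset(d["hypo"]),
                   delta_beta_min=d["delta_beta_min"], fdr_q=d["fdr_q"], route=d["route"])
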