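"""Plain-text I/O: the TSV dialects used by every stage.

All tables are tab-separated with a header row. Matrices are features x
samples with the feature id in the first column; the LFQ dialect adds a
``peptide_count`` column after the feature id and writes missing
intensities as ``NA``. Fraction schemes round-trip through YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .design import CohortDesign
from .matrices import ExpressionMatrix
from .polysome import FractionScheme, PolysomeTrace
from .simulate import AscorbateProfile, SimulationTruth

NA = "NA"


def write_design(design: CohortDesign, path) -> None:
    design.samples.to_csv(path, sep="\t", index=False)


def read_design(path) -> CohortDesign:
    return CohortDesign(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_ascorbate(profile: AscorbateProfile, path) -> None:
    profile.values.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def read_ascorbate(path) -> AscorbateProfile:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return AscorbateProfile(df.iloc[:, 0])


def write_matrix(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    if m.layer == "LFQ":
        out.insert(0, "peptide_count", m.peptide_counts)
    out.rename_axis(m.values.index.name or "feature_id").to_csv(
        path, sep="\t", na_rep=NA
    )


def read_matrix(path, layer: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if layer == "LFQ":
        pep = df.pop("peptide_count").astype(int)
        return ExpressionMatrix(df, layer="LFQ", peptide_counts=pep)
    return ExpressionMatrix(df, layer=layer)


def write_truth(truth: SimulationTruth, path) -> None:
    out = truth.genes.rename_axis("gene_id").copy()
    out["censor_log2"] = truth.censor_log2
    out.to_csv(path, sep="\t")


def read_truth(path) -> SimulationTruth:
    # keep_default_na: the gene class literal "null" must survive parsing
    df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     keep_default_na=False, na_values=[""])
    for col in df.columns:
        if col != "gene_class":
            df[col] = pd.to_numeric(df[col])
    censor = float(df.pop("censor_log2").iloc[0])
    return SimulationTruth(genes=df, censor_log2=censor)


def write_trace(trace: PolysomeTrace, path) -> None:
    pd.DataFrame(
        {"position": trace.positions, "absorbance": trace.absorbance}
    ).to_csv(path, sep="\t", index=False)


def read_trace(path) -> PolysomeTrace:
    df = pd.read_csv(path, sep="\t")
    return PolysomeTrace(
        positions=df["position"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def write_scheme(scheme: FractionScheme, path) -> None:
    doc = {
        "intervals": {k: [float(a), float(b)] for k, (a, b) in scheme.intervals.items()},
        "polysomal": list(scheme.polysomal),
    }
    if scheme.pools:
        doc["pools"] = {k: [float(a), float(b)] for k, (a, b) in scheme.pools.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scheme(path) -> FractionScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return FractionScheme(
        intervals={k: tuple(v) for k, v in doc["intervals"].items()},
        polysomal=tuple(doc["polysomal"]),
        pools={k: tuple(v) for k, v in doc.get("pools", {}).items()} or None,
    )


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fraction": str})


def write_records(records: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    """Write any per-feature record table (correlation, differential,
    quadrant) with its feature-id index as the first column."""
    records.rename_axis(index_label).to_csv(path, sep="\t", na_rep=NA)
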