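"""TSV readers/writers for the pipeline's interchange formats.

All tabular files are tab-separated with a header row. Beta matrices are
probes x samples with a ``probe_id`` index column; expression matrices are
gene x sample with a ``gene`` index column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, ProbeAnnotation, ReferenceProfiles


def read_beta_tsv(path: str | Path) -> BetaMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return BetaMatrix.from_frame(frame)


def write_beta_tsv(beta: BetaMatrix, path: str | Path) -> None:
    beta.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_annotation_tsv(path: str | Path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t",
                        dtype={"probe_id": str, "chr": str, "gene": str},
                        keep_default_na=False, na_values=[])
    table["pos"] = table["pos"].astype(int)
    table["snp_flag"] = table["snp_flag"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    return ProbeAnnotation(table)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mutations_tsv(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return table.set_index("sample_id")["n_nonsynonymous"]


def read_references_tsv(path: str | Path) -> ReferenceProfiles:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return ReferenceProfiles(list(table["probe_id"]),
                             table["beta_epithelial"].to_numpy(float),
                             table["beta_adipose"].to_numpy(float))


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def read_dmbmi_tsv(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return table.set_index("sample_id")["dm_bmi"]
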