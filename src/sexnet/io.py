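"""Readers and writers for the pipeline's plain-text dialects.

Count tables are TSV with the gene id in the first column and one column
per sample, accompanied by a sample sheet TSV (``sample_id``, ``sex``).
Bias tables are two-column TSV (gene id, bias) matching the
``gene_bias.txt`` dialect.  Gene lists are one id per line.
"""

from __future__ import annotations

import pandas as pd

from .sexbias import ExpressionMatrix

__all__ = [
    "read_counts", "write_counts",
    "read_sample_sheet", "write_sample_sheet",
    "read_expression",
    "read_bias_table", "write_bias_table",
    "read_gene_list",
]


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> dict[str, str]:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "sex"} <= set(sheet.columns):
        raise ValueError(
            f"{path}: sample sheet needs 'sample_id' and 'sex' columns")
    return dict(zip(sheet["sample_id"].astype(str), sheet["sex"]))


def write_sample_sheet(sample_sex: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\n")
        for sid, sex in sample_sex.items():
            fh.write(f"{sid}\t{sex}\n")


def read_expression(counts_path, sheet_path) -> ExpressionMatrix:
    """Count table + sample sheet → validated expression matrix."""
    return ExpressionMatrix(read_counts(counts_path),
                            read_sample_sheet(sheet_path))


def read_bias_table(path) -> pd.Series:
    """Two-column (gene, bias) file, with or without a header line."""
    bias = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                       names=["gene", "bias"], dtype={"gene": str})
    if bias.empty:
        return pd.Series(dtype=float, name="bias")
    # tolerate a header row
    first = bias.iloc[0]["bias"]
    try:
        float(first)
    except (TypeError, ValueError):
        bias = bias.iloc[1:]
    return pd.Series(bias["bias"].astype(float).to_numpy(),
                     index=bias["gene"].to_numpy(), name="bias")


def write_bias_table(bias: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for gene, b in bias.items():
            fh.write(f"{gene}\t{b:.10g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
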