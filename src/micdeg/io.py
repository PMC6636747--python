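"""Reading and writing expression matrices, phenotype files and results.

Matrices are tab- or comma-delimited (sniffed from the header line), genes
as rows: gene IDs in the first column, sample IDs in the header.  A
phenotype file has two columns, sample ID and label (0 = control,
1 = case); samples are aligned by ID, not by file order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset

__all__ = [
    "read_expression_matrix",
    "read_phenotype",
    "read_dataset",
    "write_expression_matrix",
    "write_phenotype",
    "write_dataset",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if "\t" in first else ","


def read_expression_matrix(path, transpose: bool = False) -> pd.DataFrame:
    """Read a genes x samples matrix; index = gene IDs, columns = sample IDs."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns found")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample ID {dup!r}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(f"{path}: missing value at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    try:
        num = df.astype(float)
    except ValueError:
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}") from None
    return num.T if transpose else num


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_phenotype(path, sample_ids) -> np.ndarray:
    """Read sample->label mapping and align it to ``sample_ids`` order."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        # maybe a header row: retry treating first row as header
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns (sample, label)")
    # drop a header-like first row (non-numeric label)
    if not _is_number(df.iloc[0, 1]):
        df = df.iloc[1:]
    mapping = {}
    for sid, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if sid in mapping:
            raise ValueError(f"{path}: sample {sid!r} listed twice")
        if lab not in ("0", "1", "0.0", "1.0"):
            raise ValueError(f"{path}: label for {sid!r} must be 0 or 1, got {lab!r}")
        mapping[sid] = int(float(lab))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"{path}: no phenotype for sample {missing[0]!r}")
    return np.array([mapping[s] for s in sample_ids], dtype=int)


def read_dataset(matrix_path, phenotype_path, de_mask_path=None,
                 transpose: bool = False) -> ExpressionDataset:
    df = read_expression_matrix(matrix_path, transpose=transpose)
    pheno = read_phenotype(phenotype_path, list(df.columns))
    if de_mask_path is not None:
        mask_df = pd.read_csv(de_mask_path, sep=_sniff_delimiter(Path(de_mask_path)),
                              index_col=0)
        mask = mask_df.iloc[:, 0].reindex(df.index).astype(bool).to_numpy()
    else:
        mask = np.zeros(df.shape[0], dtype=bool)
    return ExpressionDataset(matrix=df.to_numpy(), phenotype=pheno,
                             de_mask=mask, gene_ids=list(df.index),
                             sample_ids=list(df.columns))


def write_expression_matrix(path, matrix, gene_ids, sample_ids,
                            sep: str = "\t") -> None:
    pd.DataFrame(matrix, index=pd.Index(gene_ids, name="gene"),
                 columns=sample_ids).to_csv(path, sep=sep)


def write_phenotype(path, sample_ids, phenotype, sep: str = "\t") -> None:
    pd.DataFrame({"sample": sample_ids,
                  "label": np.asarray(phenotype, dtype=int)}
                 ).to_csv(path, sep=sep, index=False, header=False)


def write_dataset(out_dir, dataset: ExpressionDataset, stem: str = "dataset") -> dict:
    """Write matrix / phenotype / DE-mask TSVs for one dataset; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{stem}.matrix.tsv",
        "phenotype": out_dir / f"{stem}.phenotype.tsv",
        "de_mask": out_dir / f"{stem}.de_mask.tsv",
    }
    write_expression_matrix(paths["matrix"], dataset.matrix,
                            dataset.gene_ids, dataset.sample_ids)
    write_phenotype(paths["phenotype"], dataset.sample_ids, dataset.phenotype)
    pd.DataFrame({"gene": dataset.gene_ids,
                  "de": dataset.de_mask.astype(int)}
                 ).to_csv(paths["de_mask"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
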