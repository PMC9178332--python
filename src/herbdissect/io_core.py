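"""Readers, writers and validation for the tabular inputs and outputs.

All tables are tab-separated UTF-8 with a single header row.  In memory the
pipeline uses plain pandas/NumPy containers behind light validation wrappers:

* count matrix    -- ``pd.DataFrame`` (genes x samples, non-negative ints)
* sample table    -- ``pd.DataFrame`` with columns sample_id, treatment, replicate
* gene lengths    -- ``pd.Series`` (gene id -> length in bases)
* annotation map  -- ``dict[str, set[str]]`` (term id -> gene ids)
* expression (TPM)-- ``pd.DataFrame`` (genes x samples, columns sum to 1e6)
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd

logger = logging.getLogger("herbdissect")

TPM_SCALE = 1_000_000.0


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; ``verbose`` enables DEBUG level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


class FormatError(ValueError):
    """A table violated the expected layout or value constraints."""


# ---------------------------------------------------------------------------
# validation


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix; returns it with int64 dtype."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count matrix contains non-numeric cells")
    if np.isnan(values.astype(float)).any():
        g, s = np.argwhere(np.isnan(values.astype(float)))[0]
        raise FormatError(
            f"missing count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise FormatError(
            f"non-integer count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    out = counts.astype(np.int64)
    out.index.name = "gene_id"
    return out


def validate_samples(samples: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check a sample table (sample_id, treatment, replicate)."""
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    if counts is not None:
        unknown = set(samples["sample_id"]) - set(counts.columns)
        if unknown:
            raise FormatError(f"sample ids absent from count matrix: {sorted(unknown)}")
    return samples.reset_index(drop=True)


def validate_lengths(lengths: pd.Series, counts: pd.DataFrame | None = None) -> pd.Series:
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise FormatError(f"non-positive length for gene {bad!r}")
    if counts is not None:
        missing = set(counts.index) - set(lengths.index)
        if missing:
            raise FormatError(f"gene lengths missing for: {sorted(missing)[:5]}")
    return lengths.astype(np.int64)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_counts(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str}))


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_lengths(df.iloc[:, 0])


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id TAB term_id) -> term id -> gene set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("annotation table needs two columns: gene_id, term_id")
    gene_col, term_col = df.columns[:2]
    ann: dict[str, set[str]] = {}
    for term, sub in df.groupby(term_col):
        ann[str(term)] = set(sub[gene_col])
    return ann


def write_annotation(ann: dict[str, set[str]], path) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for t in sorted(ann)
        for g in sorted(ann[t])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# TPM


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convert counts to transcripts per million.

    TPM_gs = 1e6 * (c_gs / L_g) / sum_h (c_hs / L_h); every column of the
    result sums to 1e6.  Raises on an all-zero sample (undefined rate).
    """
    lengths = validate_lengths(lengths, counts)
    rate = counts.to_numpy(dtype=float) / lengths.loc[counts.index].to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = counts.columns[np.argwhere(colsum == 0)[0][0]]
        raise FormatError(f"sample {bad!r} has zero total counts; TPM undefined")
    tpm = TPM_SCALE * rate / colsum
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def filter_low_tpm(expr: pd.DataFrame, threshold: float = 1.0, per_sample: bool = False) -> pd.DataFrame:
    """Drop weakly expressed genes (default rule: mean TPM across samples < threshold).

    ``per_sample=True`` instead requires every sample to reach the threshold.
    Gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if per_sample:
        keep = (expr >= threshold).all(axis=1)
    else:
        keep = expr.mean(axis=1) >= threshold
    return expr.loc[keep]
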