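"""Reading, writing and filtering of expression matrices, clinical tables and signatures.

Expression matrices are tab-delimited with identifiers in the first row and
column (a GEO series-matrix-like dialect once ``!``-prefixed comment lines are
stripped).  Matrices are held genes x samples in a :class:`ExpressionDataset`
regardless of the on-disk orientation.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ClinicalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_signatures",
    "write_signatures",
    "filter_expr_variance",
    "filter_expr_presence",
    "collapse_probes_to_genes",
]

#: sentinel gene id used for intercept rows in signature TSV files
INTERCEPT_KEY = "(intercept)"

#: default presence-filter threshold: log2 of an intensity of 100
LOG2_100 = math.log2(100.0)


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: dict[str, int] = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    dups = sorted(k for k, c in seen.items() if c > 1)
    if dups:
        shown = ", ".join(dups[:10])
        raise ValueError(f"duplicate {what}: {shown}" + (" ..." if len(dups) > 10 else ""))


@dataclass
class ExpressionDataset:
    """A log-scale expression matrix (genes x samples) with identifiers.

    Parameters
    ----------
    name
        Free-text dataset label (e.g. a cohort name).
    matrix
        DataFrame of log-scale intensities, index = gene/probe ids,
        columns = sample ids.
    platform
        Free-text platform label.
    log_base
        Base of the logarithm the intensities are on.  Declared only;
        no rescaling is ever performed implicitly.
    """

    name: str
    matrix: pd.DataFrame
    platform: str = ""
    log_base: float = 2.0

    def __post_init__(self) -> None:
        _check_unique(self.matrix.index.astype(str), "gene_ids")
        _check_unique(self.matrix.columns.astype(str), "sample_ids")
        values = self.matrix.to_numpy()
        if values.size and not np.isfinite(values.astype(float, copy=False)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))
            g, s = bad[0]
            raise ValueError(
                f"non-finite expression value at gene {self.matrix.index[g]!r}, "
                f"sample {self.matrix.columns[s]!r}"
            )
        if self.log_base <= 0:
            raise ValueError("log_base must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns.astype(str))

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in genes if g in self.matrix.index]
        return replace(self, matrix=self.matrix.loc[keep])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: survival time, event, endpoint, chemoresponse.

    ``endpoint`` is one of ``PFS``/``OS``; ``chemoresponse`` is
    ``sensitive``/``resistant``/``unknown``.  ``time_unit`` records whether
    times are months or days; it is metadata only.
    """

    frame: pd.DataFrame
    time_unit: str = "months"

    REQUIRED = ("sample_id", "time", "event")
    ENDPOINTS = ("PFS", "OS")
    CHEMO = ("sensitive", "resistant", "unknown")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if "endpoint" not in self.frame.columns:
            self.frame = self.frame.assign(endpoint="PFS")
        if "chemoresponse" not in self.frame.columns:
            self.frame = self.frame.assign(chemoresponse="unknown")
        _check_unique(self.frame["sample_id"].astype(str), "sample_ids")
        t = self.frame["time"].to_numpy(dtype=float)
        if np.any(t[np.isfinite(t)] < 0):
            raise ValueError("survival times must be nonnegative")
        ev = self.frame["event"].dropna().to_numpy(dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0/1")
        bad_ep = set(self.frame["endpoint"].dropna()) - set(self.ENDPOINTS)
        if bad_ep:
            raise ValueError(f"unknown endpoint labels: {sorted(bad_ep)}")
        bad_cr = set(self.frame["chemoresponse"].dropna()) - set(self.CHEMO)
        if bad_cr:
            raise ValueError(f"unknown chemoresponse labels: {sorted(bad_cr)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"].astype(str))

    def aligned_to(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Rows reindexed to ``sample_ids`` (missing samples become NaN rows)."""
        idx = self.frame.set_index("sample_id")
        return idx.reindex(list(sample_ids))


def _strip_comments(path: str | Path, comment: str = "!") -> _io.StringIO:
    lines = []
    with open(path, "rt") as fh:
        for line in fh:
            if not line.startswith(comment):
                lines.append(line)
    return _io.StringIO("".join(lines))


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv_genes_by_samples",
    name: str | None = None,
    platform: str = "",
    log_base: float = 2.0,
) -> ExpressionDataset:
    """Read a TSV expression matrix, normalising orientation to genes x samples.

    ``dialect`` is ``tsv_genes_by_samples`` (rows are genes) or
    ``tsv_samples_by_genes`` (rows are samples, transposed on read).
    ``!``-prefixed lines are ignored.  Duplicate identifiers and non-numeric
    cells raise ``ValueError`` naming the offenders.
    """
    if dialect not in ("tsv_genes_by_samples", "tsv_samples_by_genes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(_strip_comments(path), sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[gi, si]!r} at row {raw.index[gi]!r}, "
            f"column {raw.columns[si]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {raw.index[gi]!r}, column {raw.columns[si]!r}")
    if dialect == "tsv_samples_by_genes":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionDataset(
        name=name if name is not None else Path(path).stem,
        matrix=numeric.astype(float),
        platform=platform,
        log_base=log_base,
    )


def write_expression_matrix(
    ds: ExpressionDataset, path: str | Path, dialect: str = "tsv_genes_by_samples"
) -> None:
    """Write the matrix to TSV at full float precision (round-trip safe)."""
    mat = ds.matrix if dialect == "tsv_genes_by_samples" else ds.matrix.T
    if dialect not in ("tsv_genes_by_samples", "tsv_samples_by_genes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mat.to_csv(path, sep="\t", index_label="id", float_format=None)


def read_clinical_table(path: str | Path, time_unit: str = "months") -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(frame=frame, time_unit=time_unit)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_signatures(path: str | Path) -> dict[str, "GeneSignature"]:
    """Read signature definitions from TSV (columns: signature, gene, coefficient).

    Rows whose gene is ``(intercept)`` set the signature's intercept.
    Returns a mapping signature name -> :class:`~pathmeta.scoring.GeneSignature`,
    preserving file order.
    """
    from .scoring import GeneSignature

    frame = pd.read_csv(path, sep="\t", dtype={"signature": str, "gene": str})
    out: dict[str, GeneSignature] = {}
    for sig_name, grp in frame.groupby("signature", sort=False):
        intercept = 0.0
        entries: dict[str, float] = {}
        for _, row in grp.iterrows():
            if row["gene"] == INTERCEPT_KEY:
                intercept = float(row["coefficient"])
            else:
                if row["gene"] in entries:
                    raise ValueError(f"duplicate gene {row['gene']!r} in signature {sig_name!r}")
                entries[row["gene"]] = float(row["coefficient"])
        out[sig_name] = GeneSignature(name=sig_name, entries=entries, intercept=intercept)
    return out


def write_signatures(signatures: Iterable, path: str | Path) -> None:
    rows = []
    for sig in signatures:
        for gene, coef in sig.entries.items():
            rows.append((sig.name, gene, coef))
        if sig.intercept != 0.0:
            rows.append((sig.name, INTERCEPT_KEY, sig.intercept))
    pd.DataFrame(rows, columns=["signature", "gene", "coefficient"]).to_csv(
        path, sep="\t", index=False
    )


def filter_expr_variance(
    ds: ExpressionDataset,
    min_log_expr: float = 7.0,
    min_variance: float = 0.5,
    aggregate: str = "max",
) -> ExpressionDataset:
    """Keep informative genes: aggregate log expression >= ``min_log_expr`` and
    across-sample variance >= ``min_variance``.

    ``aggregate`` selects how the per-gene expression level is summarised
    before comparison with ``min_log_expr`` (``max`` by default, which keeps
    genes expressed in any subgroup; ``mean``/``min`` available for matching
    other conventions).  Variance uses the n-1 denominator.  Gene order is
    preserved; retained values are untouched.
    """
    agg_funcs = {"max": np.max, "mean": np.mean, "min": np.min}
    if aggregate not in agg_funcs:
        raise ValueError(f"aggregate must be one of {sorted(agg_funcs)}")
    values = ds.matrix.to_numpy(dtype=float)
    level = agg_funcs[aggregate](values, axis=1)
    var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(values))
    keep = (level >= min_log_expr) & (var >= min_variance)
    if not keep.any():
        warnings.warn(
            f"variance filter removed every gene of dataset {ds.name!r}", stacklevel=2
        )
    return replace(ds, matrix=ds.matrix.loc[keep])


def filter_expr_presence(
    ds: ExpressionDataset,
    threshold: float = LOG2_100,
    min_fraction: float = 0.25,
) -> ExpressionDataset:
    """Keep genes with expression >= ``threshold`` in >= ``min_fraction`` of samples.

    Both comparisons are inclusive.  Defaults correspond to log2(100) present
    in at least 25% of arrayed samples.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    values = ds.matrix.to_numpy(dtype=float)
    frac = (values >= threshold).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn(
            f"presence filter removed every gene of dataset {ds.name!r}", stacklevel=2
        )
    return replace(ds, matrix=ds.matrix.loc[keep])


def collapse_probes_to_genes(
    ds: ExpressionDataset, mapping: Mapping[str, str] | pd.Series
) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene.

    The probe with the highest mean expression represents its gene; ties are
    broken by lexicographically smallest probe id.  Probes absent from
    ``mapping`` are dropped.
    """
    if isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    if not mapping:
        raise ValueError("probe-to-gene mapping is empty")
    probes = [p for p in ds.gene_ids if p in mapping]
    if not probes:
        warnings.warn("no probes of the dataset are covered by the mapping", stacklevel=2)
        return replace(ds, matrix=ds.matrix.iloc[0:0])
    means = ds.matrix.loc[probes].mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(probes):  # lexicographic order makes ties deterministic
        gene = mapping[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    chosen = sorted(best.items(), key=lambda kv: kv[0])
    mat = ds.matrix.loc[[p for _, p in chosen]]
    mat.index = pd.Index([g for g, _ in chosen], name=ds.matrix.index.name)
    return replace(ds, matrix=mat)
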