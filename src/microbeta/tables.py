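"""Aligned sample x taxon abundance and sample x parameter environment tables.

Both tables are thin, validated wrappers around a numeric matrix with ordered
row (sample) and column (taxon / parameter) identifiers.  Abundances may be
relative fractions produced by amplicon or metagenomic sequencing pipelines,
or absolute counts where those are measurable; the ``mode`` flag records
which, and relative tables are checked for (soft) closure.

On-disk format is plain TSV: header row of column identifiers, first column
of sample identifiers, numeric body.  An optional import path converts R
serialized ``.RData`` tables through ``Rscript``.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Mode = Literal["relative", "absolute"]

#: Slack allowed on relative-abundance row sums (taxon filtering legitimately
#: breaks exact closure, so sums above 1 by more than this only warn).
ROW_SUM_TOL = 1e-6


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what} identifiers: {dups}")


def _check_finite(values: np.ndarray, rows: Sequence[str], cols: Sequence[str],
                  what: str) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise TableValidationError(
            f"{what} contains a non-finite value at sample "
            f"{rows[r]!r}, column {cols[c]!r}")


@dataclass(frozen=True)
class AbundanceTable:
    """N samples x d taxa nonnegative abundance matrix."""

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    values: np.ndarray
    mode: Mode = "relative"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TableValidationError("abundance values must be a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableValidationError(
                f"value shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa")
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "taxon_ids", tuple(map(str, self.taxon_ids)))
        object.__setattr__(self, "values", values)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        _check_finite(values, self.sample_ids, self.taxon_ids, "abundance table")
        neg = values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise TableValidationError(
                f"negative abundance {values[r, c]} at sample "
                f"{self.sample_ids[r]!r}, taxon {self.taxon_ids[c]!r}")
        if self.mode not in ("relative", "absolute"):
            raise TableValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            over = sums > 1 + ROW_SUM_TOL
            if over.any():
                k = int(np.argmax(over))
                logger.warning(
                    "relative abundance row sum %.6f > 1 at sample %r",
                    sums[k], self.sample_ids[k])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.taxon_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: Mode = "relative") -> "AbundanceTable":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=float), mode)

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return replace(self, sample_ids=tuple(ids), values=self.values[idx])

    def select_taxa(self, ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in ids]
        return replace(self, taxon_ids=tuple(ids), values=self.values[:, idx])


@dataclass(frozen=True)
class EnvironmentTable:
    """N samples x m environmental parameter matrix (mixed units)."""

    sample_ids: tuple[str, ...]
    param_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TableValidationError("environment values must be a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.param_ids)):
            raise TableValidationError(
                f"value shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.param_ids)} parameters")
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "param_ids", tuple(map(str, self.param_ids)))
        object.__setattr__(self, "values", values)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.param_ids, "parameter")
        _check_finite(values, self.sample_ids, self.param_ids, "environment table")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_params(self) -> int:
        return len(self.param_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.param_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnvironmentTable":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def select_samples(self, ids: Sequence[str]) -> "EnvironmentTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return replace(self, sample_ids=tuple(ids), values=self.values[idx])

    def select_params(self, ids: Sequence[str]) -> "EnvironmentTable":
        idx = [self.param_ids.index(p) for p in ids]
        return replace(self, param_ids=tuple(ids), values=self.values[:, idx])


def _read_tsv(path: str | Path, what: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
    except ValueError as exc:
        raise TableValidationError(f"cannot parse {what} table {path}: {exc}") from exc
    frame.index = frame.index.map(str)
    non_numeric = [c for c in frame.columns
                   if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        col = non_numeric[0]
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        where = f" (e.g. sample {bad.index[0]!r} = {bad.iloc[0]!r})" if len(bad) else ""
        raise TableValidationError(
            f"non-numeric cell in {what} column {col!r}{where}")
    nan = frame.isna()
    if nan.to_numpy().any():
        r = nan.any(axis=1).idxmax()
        c = nan.loc[r][nan.loc[r]].index[0]
        raise TableValidationError(
            f"missing value in {what} at sample {r!r}, column {c!r}")
    return frame


def read_abundance(path: str | Path, mode: Mode = "relative") -> AbundanceTable:
    """Read a samples x taxa TSV (header = taxon ids, first column = sample ids)."""
    return AbundanceTable.from_frame(_read_tsv(path, "abundance"), mode=mode)


def read_environment(path: str | Path) -> EnvironmentTable:
    """Read a samples x parameters TSV."""
    return EnvironmentTable.from_frame(_read_tsv(path, "environment"))


def write_table(table: AbundanceTable | EnvironmentTable, path: str | Path) -> None:
    """Write either table type as TSV with full float precision."""
    table.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def align_tables(a: AbundanceTable, e: EnvironmentTable
                 ) -> tuple[AbundanceTable, EnvironmentTable]:
    """Restrict both tables to their shared samples, in abundance-table order.

    Dropped sample identifiers are logged.  Raises if the tables share no
    samples.  Idempotent: aligning aligned tables is the identity.
    """
    env_ids = set(e.sample_ids)
    shared = [s for s in a.sample_ids if s in env_ids]
    if not shared:
        raise TableValidationError("abundance and environment tables share no samples")
    dropped = sorted((set(a.sample_ids) | env_ids) - set(shared))
    if dropped:
        logger.info("align_tables dropped %d samples: %s", len(dropped), dropped)
    return a.select_samples(shared), e.select_samples(shared)


_RDATA_SCRIPT = """\
args <- commandArgs(trailingOnly = TRUE)
env <- new.env()
nm <- load(args[1], envir = env)
obj <- if (length(args) > 2 && nzchar(args[3])) get(args[3], envir = env) else get(nm[1], envir = env)
write.table(as.data.frame(obj), file = args[2], sep = "\\t",
            quote = FALSE, col.names = NA)
"""


def read_rdata_table(path: str | Path, object_name: str | None = None) -> pd.DataFrame:
    """Load a matrix/data.frame from an ``.RData`` file via ``Rscript``.

    Used for the optional import of externally published R benchmark tables.
    Requires ``Rscript`` on PATH.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tempfile.TemporaryDirectory() as tmp:
        script = Path(tmp) / "convert.R"
        out = Path(tmp) / "table.tsv"
        script.write_text(_RDATA_SCRIPT)
        cmd = ["Rscript", "--vanilla", str(script), str(path), str(out),
               object_name or ""]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"Rscript conversion failed: {proc.stderr.strip()}")
        frame = pd.read_csv(out, sep="\t", index_col=0)
    frame.index = frame.index.map(str)
    return frame
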