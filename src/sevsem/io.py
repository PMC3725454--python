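"""File input/output: moment tables, raw score tables, fit reports.

Moment-table CSV layout (the bundled study table ships in it)::

    # n = 283
    ,ADS,PACS,...
    mean,40.25,17.92,...
    sd,7.31,6.61,...
    ADS,1,0.5,...
    PACS,0.5,1,...

i.e. a variable-name header, a mean row, an SD row, then the square
correlation block.  A ``# n = <int>`` comment line carries the sample
size.  Raw score tables are ordinary one-row-per-subject CSVs with a
header; rows with missing values are listwise-deleted and the count is
logged.  The ``%`` in "BINGE%" is sanitized to ``BINGE_PCT`` so outputs
stay portable identifiers.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError
from .sem_core import FitResult, SampleMoments

logger = logging.getLogger("sevsem")

__all__ = ["load_moments_csv", "write_moments_csv", "load_raw_csv", "write_fit_outputs",
           "sanitize_name"]


def sanitize_name(name: str) -> str:
    return name.strip().replace("%", "_PCT")


def load_moments_csv(path) -> SampleMoments:
    """Read a correlation + SD + mean table into :class:`SampleMoments`."""
    path = Path(path)
    text = path.read_text().splitlines()
    n = None
    rows = []
    for line in text:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.search(r"n\s*=\s*(\d+)", s)
            if m:
                n = int(m.group(1))
            continue
        rows.append([c.strip() for c in s.split(",")])
    if n is None:
        raise InputError(f"{path}: missing '# n = <int>' sample-size line")
    if len(rows) < 4:
        raise InputError(f"{path}: expected header, mean, sd and a correlation block")
    names = [sanitize_name(c) for c in rows[0][1:]]
    p = len(names)

    def numeric_row(row, label):
        if row[0].lower() != label and label not in ("corr",):
            raise InputError(f"{path}: expected a '{label}' row, found {row[0]!r}")
        if len(row) != p + 1:
            raise InputError(f"{path}: row {row[0]!r} has {len(row) - 1} values, expected {p}")
        try:
            return np.array([float(x) for x in row[1:]])
        except ValueError as e:
            raise InputError(f"{path}: non-numeric cell in row {row[0]!r}: {e}")

    means = numeric_row(rows[1], "mean")
    sds = numeric_row(rows[2], "sd")
    block = rows[3:]
    if len(block) != p:
        raise InputError(f"{path}: correlation block has {len(block)} rows, expected {p}")
    R = np.empty((p, p))
    for i, row in enumerate(block):
        if sanitize_name(row[0]) != names[i]:
            raise InputError(f"{path}: correlation row {i + 1} labeled {row[0]!r}, expected {names[i]!r}")
        R[i] = numeric_row(row, "corr")
    for i in range(p):
        if R[i, i] != 1.0:
            raise InputError(f"{path}: correlation diagonal at {names[i]!r} is {R[i, i]}, must be 1")
        for j in range(p):
            if abs(R[i, j]) > 1:
                raise InputError(f"{path}: correlation ({names[i]}, {names[j]}) = {R[i, j]} out of [-1, 1]")
    if np.max(np.abs(R - R.T)) > 1e-12:
        raise InputError(f"{path}: correlation block is not symmetric")
    R = 0.5 * (R + R.T)
    if np.any(sds <= 0):
        bad = names[int(np.argmin(sds))]
        raise InputError(f"{path}: SD for {bad!r} must be positive")
    return SampleMoments.from_correlation(R, sds, n, names, means)


def write_moments_csv(moments: SampleMoments, path) -> None:
    sd = np.sqrt(np.diag(moments.S))
    R = moments.S / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    means = moments.means if moments.means is not None else np.zeros(moments.p)
    lines = [f"# n = {moments.n}", "," + ",".join(moments.names)]
    lines.append("mean," + ",".join(f"{v:.10g}" for v in means))
    lines.append("sd," + ",".join(f"{v:.10g}" for v in sd))
    for i, name in enumerate(moments.names):
        lines.append(name + "," + ",".join(f"{v:.10g}" for v in R[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_raw_csv(path, group_column: Optional[str] = None):
    """Read a raw score table; listwise-delete incomplete rows (logged).

    Returns a DataFrame, or (DataFrame, groups Series) when
    ``group_column`` is given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [sanitize_name(c) for c in df.columns]
    if group_column is not None:
        group_column = sanitize_name(group_column)
        if group_column not in df.columns:
            raise InputError(f"{path}: no group column {group_column!r}")
    value_cols = [c for c in df.columns if c != group_column]
    for c in value_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df[c][coerced.isna() & df[c].notna()]
            if len(bad):
                raise InputError(
                    f"{path}: non-numeric cell {bad.iloc[0]!r} in column {c!r}, row {bad.index[0] + 2}"
                )
            df[c] = coerced
    complete = df.dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("%s: excluded %d incomplete row(s), %d retained", path.name, dropped, len(complete))
    complete = complete.reset_index(drop=True)
    if group_column is None:
        return complete
    groups = complete[group_column]
    if groups.nunique() < 1:
        raise InputError(f"{path}: no rows remain to define groups in {group_column!r}")
    if (groups.astype(str).str.strip() == "").any():
        raise InputError(f"{path}: empty group label in column {group_column!r}")
    return complete.drop(columns=[group_column]), groups


def write_fit_outputs(fit: FitResult, out_dir, stem: str = "fit") -> dict:
    """Emit the full fit as JSON and the parameter table as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{stem}.json"
    tsv_path = out / f"{stem}_parameters.tsv"
    json_path.write_text(fit.to_json() + "\n")
    fit.params.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
    return {"json": json_path, "tsv": tsv_path}
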