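"""Ct-table data model, readers/writers, and validation.

The central container is :class:`CtMatrix`: quantification-cycle (Ct)
values for *k* candidate genes measured in *n* samples, plus optional
per-sample condition labels (e.g. tissue name or sex) and replicate ids.
Every downstream stability method consumes this object.

Two on-disk layouts are supported:

* **long** — one measurement per row, columns ``sample, group, replicate,
  gene, ct`` (``group`` and ``replicate`` optional);
* **wide** — genes as rows and samples as columns (or transposed).

Gene and sample order is taken from first occurrence in the file and is
the canonical order used for deterministic tie-breaking everywhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum matrix shape accepted by the stability methods.
MIN_GENES = 2
MIN_SAMPLES = 3


class CtValidationError(ValueError):
    """A Ct matrix violates a structural invariant."""


class CtLoadError(ValueError):
    """A Ct table file cannot be parsed into a valid matrix."""


def _first_occurrence(values: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass(frozen=True)
class CtMatrix:
    """Genes x samples Ct values with sample metadata.

    Parameters
    ----------
    ct
        DataFrame of Ct values, genes as the index, samples as columns.
        All cells must be present and finite.
    group_of
        Optional map sample -> condition label. When given it must cover
        every sample.
    replicate_of
        Optional map sample -> (biological) replicate id.
    """

    ct: pd.DataFrame
    group_of: Mapping[str, str] | None = None
    replicate_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.ct, pd.DataFrame):
            raise CtValidationError("ct must be a pandas DataFrame (genes x samples)")
        ct = self.ct.copy()
        ct.index = ct.index.astype(str)
        ct.columns = ct.columns.astype(str)
        if ct.index.duplicated().any():
            dup = ct.index[ct.index.duplicated()][0]
            raise CtValidationError(f"duplicate gene identifier: {dup!r}")
        if ct.columns.duplicated().any():
            dup = ct.columns[ct.columns.duplicated()][0]
            raise CtValidationError(f"duplicate sample identifier: {dup!r}")
        if ct.shape[0] < MIN_GENES:
            raise CtValidationError(
                f"need at least {MIN_GENES} genes, got {ct.shape[0]}"
            )
        if ct.shape[1] < MIN_SAMPLES:
            raise CtValidationError(
                f"need at least {MIN_SAMPLES} samples, got {ct.shape[1]}"
            )
        try:
            values = ct.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise CtValidationError(f"non-numeric Ct value: {exc}") from exc
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CtValidationError(
                f"missing or non-finite Ct for gene {ct.index[i]!r}, "
                f"sample {ct.columns[j]!r}"
            )
        ct = pd.DataFrame(values, index=ct.index, columns=ct.columns)
        ct.index.name = "gene"
        ct.columns.name = "sample"
        object.__setattr__(self, "ct", ct)
        if self.group_of is not None:
            group_of = {str(k): str(v) for k, v in dict(self.group_of).items()}
            missing = [s for s in ct.columns if s not in group_of]
            if missing:
                raise CtValidationError(
                    f"group label missing for sample {missing[0]!r}"
                )
            object.__setattr__(self, "group_of", group_of)
        if self.replicate_of is not None:
            object.__setattr__(
                self,
                "replicate_of",
                {str(k): str(v) for k, v in dict(self.replicate_of).items()},
            )

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def k(self) -> int:
        """Number of genes."""
        return self.ct.shape[0]

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.ct.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Ct values as a float array of shape (k, n)."""
        return self.ct.to_numpy()

    def groups(self) -> pd.Series | None:
        """Per-sample group labels aligned with :attr:`samples`, or None."""
        if self.group_of is None:
            return None
        return pd.Series(
            [self.group_of[s] for s in self.samples], index=self.samples, name="group"
        )

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-occurrence sample order."""
        g = self.groups()
        return [] if g is None else _first_occurrence(g)

    # -- operations --------------------------------------------------------

    def subset_by_group(self, groups: str | Iterable[str]) -> "CtMatrix":
        """Restrict the matrix to samples whose group is in ``groups``.

        Gene set and ordering are unchanged; sample order is preserved.
        """
        if self.group_of is None:
            raise CtValidationError("matrix carries no group labels")
        wanted = {groups} if isinstance(groups, str) else set(map(str, groups))
        known = set(self.group_of[s] for s in self.samples)
        unknown = wanted - known
        if unknown:
            raise CtValidationError(f"unknown group label: {sorted(unknown)[0]!r}")
        keep = [s for s in self.samples if self.group_of[s] in wanted]
        if len(keep) < MIN_SAMPLES:
            raise CtValidationError(
                f"subset has {len(keep)} samples; at least {MIN_SAMPLES} required"
            )
        rep = None
        if self.replicate_of is not None:
            rep = {s: self.replicate_of[s] for s in keep if s in self.replicate_of}
        return CtMatrix(
            self.ct[keep],
            group_of={s: self.group_of[s] for s in keep},
            replicate_of=rep,
        )


@dataclass(frozen=True)
class StabilityTable:
    """Per-gene stability values and ranks for one method.

    ``frame`` is indexed by gene (canonical order) with columns
    ``stability`` and ``rank``; ``tie_rule`` records the ranking
    convention carried by the ``rank`` column.
    """

    method: str
    frame: pd.DataFrame
    tie_rule: str = "ordinal"

    def __post_init__(self) -> None:
        if not {"stability", "rank"} <= set(self.frame.columns):
            raise CtValidationError("StabilityTable needs stability and rank columns")
        if (self.frame["stability"] < 0).any():
            raise CtValidationError("stability values must be >= 0")

    @property
    def stability(self) -> pd.Series:
        return self.frame["stability"]

    @property
    def rank(self) -> pd.Series:
        return self.frame["rank"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LONG_REQUIRED = ("sample", "gene", "ct")


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    *,
    orientation: str = "genes-rows",
    group_column: str = "group",
    replicate_column: str = "replicate",
    delimiter: str = ",",
    impute_missing: bool = False,
) -> CtMatrix:
    """Read a Ct table from a delimited text file.

    Long layout requires columns ``sample, gene, ct`` with optional group
    and replicate columns.  When a replicate column marks technical
    replicates of the same (gene, sample) pair they are collapsed to
    their arithmetic mean Ct before validation.  Missing Ct cells are a
    hard error unless ``impute_missing`` is set, in which case a cell is
    imputed by the mean Ct of that gene within the sample's group and the
    imputation is logged.
    """
    path = Path(path)
    if not path.exists():
        raise CtLoadError(f"no such file: {path}")
    if layout == "long":
        return _read_long(
            path,
            group_column=group_column,
            replicate_column=replicate_column,
            delimiter=delimiter,
            impute_missing=impute_missing,
        )
    if layout == "wide":
        return _read_wide(path, orientation=orientation, delimiter=delimiter)
    raise CtLoadError(f"unknown layout {layout!r} (expected 'long' or 'wide')")


def _parse_ct(text: str, gene: str, sample: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise CtLoadError(
            f"non-numeric Ct {text!r} for gene {gene!r}, sample {sample!r}"
        ) from None
    if not np.isfinite(value):
        raise CtLoadError(f"non-finite Ct for gene {gene!r}, sample {sample!r}")
    return value


def _read_long(
    path: Path,
    *,
    group_column: str,
    replicate_column: str,
    delimiter: str,
    impute_missing: bool,
) -> CtMatrix:
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, comment="#"
    )
    df.columns = [c.strip() for c in df.columns]
    missing_cols = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing_cols:
        raise CtLoadError(f"long layout requires column {missing_cols[0]!r}")
    for col in df.columns:
        df[col] = df[col].str.strip()

    has_group = group_column in df.columns
    has_rep = replicate_column in df.columns

    genes = _first_occurrence(df["gene"])
    samples = _first_occurrence(df["sample"])

    group_of: dict[str, str] | None = None
    if has_group:
        group_of = {}
        for sample, sub in df.groupby("sample", sort=False):
            labels = set(sub[group_column])
            if len(labels) > 1:
                raise CtLoadError(
                    f"inconsistent group labels for sample {sample!r}: {sorted(labels)}"
                )
            group_of[sample] = labels.pop()

    # Parse Ct values; blank cells become NaN for imputation or error later.
    parsed = np.full(len(df), np.nan)
    for i, (gene, sample, text) in enumerate(
        zip(df["gene"], df["sample"], df["ct"])
    ):
        if text == "":
            if not impute_missing:
                raise CtLoadError(
                    f"missing Ct for gene {gene!r}, sample {sample!r}"
                )
            continue
        parsed[i] = _parse_ct(text, gene, sample)
    df = df.assign(_ct=parsed)

    if has_rep:
        key = list(zip(df["gene"], df["sample"], df[replicate_column]))
        if len(key) != len(set(key)):
            seen: set = set()
            for k in key:
                if k in seen:
                    raise CtLoadError(
                        f"duplicate measurement for gene {k[0]!r}, sample {k[1]!r}, "
                        f"replicate {k[2]!r}"
                    )
                seen.add(k)
    else:
        key2 = list(zip(df["gene"], df["sample"]))
        if len(key2) != len(set(key2)):
            seen = set()
            for k2 in key2:
                if k2 in seen:
                    raise CtLoadError(
                        f"duplicate (gene, sample) pair: gene {k2[0]!r}, sample {k2[1]!r}"
                    )
                seen.add(k2)

    # Collapse technical replicates (same gene+sample, distinct replicate id)
    # to their arithmetic mean Ct.
    collapsed = df.groupby(["gene", "sample"], sort=False)["_ct"].mean()
    matrix = collapsed.unstack("sample").reindex(index=genes, columns=samples)

    replicate_of = None
    if has_rep:
        n_per = df.groupby(["gene", "sample"], sort=False)["_ct"].size()
        if (n_per > 1).any():
            logger.info(
                "collapsed technical replicates to mean Ct for %d (gene, sample) pairs",
                int((n_per > 1).sum()),
            )
        else:
            replicate_of = {
                s: r for s, r in zip(df["sample"], df[replicate_column])
            }

    nan_cells = np.argwhere(matrix.isna().to_numpy())
    if nan_cells.size:
        if not impute_missing:
            i, j = nan_cells[0]
            raise CtLoadError(
                f"missing Ct for gene {genes[i]!r}, sample {samples[j]!r}"
            )
        if group_of is None:
            i, j = nan_cells[0]
            raise CtLoadError(
                "cannot impute without group labels: missing Ct for gene "
                f"{genes[i]!r}, sample {samples[j]!r}"
            )
        for i, j in nan_cells:
            gene, sample = genes[i], samples[j]
            peers = [
                s
                for s in samples
                if group_of[s] == group_of[sample] and not np.isnan(matrix.iloc[i][s])
            ]
            if not peers:
                raise CtLoadError(
                    f"cannot impute gene {gene!r}, sample {sample!r}: no observed "
                    f"Ct in group {group_of[sample]!r}"
                )
            value = float(matrix.iloc[i][peers].mean())
            matrix.iloc[i, j] = value
            logger.warning(
                "imputed Ct for gene %r, sample %r with group-mean %.4f",
                gene,
                sample,
                value,
            )

    return CtMatrix(matrix, group_of=group_of, replicate_of=replicate_of)


def _read_wide(path: Path, *, orientation: str, delimiter: str) -> CtMatrix:
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, comment="#"
    )
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise CtLoadError("wide layout needs an id column and at least one data column")
    id_col = df.columns[0]
    ids = [v.strip() for v in df[id_col]]
    data_cols = [c.strip() for c in df.columns[1:]]
    values = np.empty((len(ids), len(data_cols)))
    for i, row_id in enumerate(ids):
        for j, col in enumerate(df.columns[1:]):
            text = str(df.iloc[i][col]).strip()
            if text == "":
                gene, sample = (
                    (row_id, data_cols[j])
                    if orientation == "genes-rows"
                    else (data_cols[j], row_id)
                )
                raise CtLoadError(
                    f"missing Ct for gene {gene!r}, sample {sample!r}"
                )
            gene, sample = (
                (row_id, data_cols[j])
                if orientation == "genes-rows"
                else (data_cols[j], row_id)
            )
            values[i, j] = _parse_ct(text, gene, sample)
    if orientation == "genes-rows":
        matrix = pd.DataFrame(values, index=ids, columns=data_cols)
    elif orientation == "samples-rows":
        matrix = pd.DataFrame(values.T, index=data_cols, columns=ids)
    else:
        raise CtLoadError(
            f"unknown orientation {orientation!r} "
            "(expected 'genes-rows' or 'samples-rows')"
        )
    return CtMatrix(matrix)


def write_ct_table(
    m: CtMatrix,
    path: str | Path,
    layout: str = "long",
    *,
    delimiter: str = ",",
) -> None:
    """Write a CtMatrix so that :func:`read_ct_table` recovers it exactly.

    Floats are written with full round-trip precision.  Long layout
    includes group and replicate columns when the matrix carries them.
    """
    path = Path(path)
    if layout == "long":
        records = []
        for gene in m.genes:
            for sample in m.samples:
                rec = {"sample": sample}
                if m.group_of is not None:
                    rec["group"] = m.group_of[sample]
                if m.replicate_of is not None and sample in m.replicate_of:
                    rec["replicate"] = m.replicate_of[sample]
                rec["gene"] = gene
                rec["ct"] = m.ct.at[gene, sample]
                records.append(rec)
        pd.DataFrame(records).to_csv(path, sep=delimiter, index=False)
    elif layout == "wide":
        out = m.ct.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep=delimiter, index=False)
    else:
        raise CtLoadError(f"unknown layout {layout!r} (expected 'long' or 'wide')")


def write_results_table(
    frame: pd.DataFrame,
    path: str | Path,
    *,
    delimiter: str = "\t",
    header_comment: str | None = None,
    index_label: str = "gene",
) -> None:
    """Write a results table as delimited text with an optional ``#`` header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=delimiter, index=True, index_label=index_label)


def write_stability_table(
    table: StabilityTable, path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write one method's stability table (gene, method, stability, rank)."""
    frame = table.frame.copy()
    frame.insert(0, "method", table.method)
    write_results_table(frame, path, delimiter=delimiter)


def read_stability_table(path: str | Path, *, delimiter: str = "\t") -> StabilityTable:
    """Read a table written by :func:`write_stability_table`."""
    df = pd.read_csv(path, sep=delimiter, comment="#", index_col="gene")
    methods = set(df["method"])
    if len(methods) != 1:
        raise CtLoadError(f"expected one method per table, found {sorted(methods)}")
    return StabilityTable(methods.pop(), df[["stability", "rank"]])
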