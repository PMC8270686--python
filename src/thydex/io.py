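"""Tabular and gene-set I/O plus the shared domain containers.

Everything downstream operates on a small set of containers:

* :class:`ExpressionMatrix` — features x samples log2 intensities,
  at probe, probeset or gene level;
* a sample sheet (:class:`pandas.DataFrame` indexed by sample id, with a
  ``group`` column and optional ``stage_weeks``);
* :class:`ProbeAnnotation` — probe id -> gene symbol;
* :class:`TermCollection` — gene-set terms (GMT);
* :class:`SuperclusterMap` — term -> (supercluster, subcluster) assignments.

All tables are tab-separated UTF-8 with a header row and "." decimals;
numbers are written with 12 significant digits so write -> read round-trips
are the identity at that precision.  Gene symbols are upper-cased on ingest
so that annotation sources with mixed-case symbols match.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("thydex")

#: canonical group labels: adult thyroid, embryonic thyroid,
#: adult tissue mix, embryonic tissue mix
GROUPS = ("AT", "ET", "AM", "EM")

#: the four group-vs-group contrasts, first-named minus second-named
COMPARISONS = {
    "comp1": ("AT", "ET"),
    "comp2": ("AT", "AM"),
    "comp3": ("AM", "EM"),
    "comp4": ("ET", "EM"),
}

FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """A file violates the declared table/gene-set format."""


class ValidationError(ValueError):
    """A parsed object violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ExpressionMatrix:
    """Feature x sample grid of log2 intensities.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    level
        One of ``"probe"``, ``"probeset"``, ``"gene"``.
    """

    values: pd.DataFrame
    level: str = "probe"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValidationError("expression matrix must be non-empty")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if self.level not in ("probe", "probeset", "gene"):
            raise ValidationError(f"unknown level {self.level!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.values.loc[:, ids].copy(), level=self.level)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.values.index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        return ExpressionMatrix(self.values.loc[ids].copy(), level=self.level)


@dataclasses.dataclass
class ProbeAnnotation:
    """probe id -> gene symbol; unannotated probes map to ``None``.

    Symbols are upper-cased on construction.  A gene symbol may own several
    probe ids but each probe maps to at most one symbol.
    """

    mapping: dict[str, str | None]

    def __post_init__(self) -> None:
        self.mapping = {
            str(p): (str(g).upper() if g is not None and str(g) != "" else None)
            for p, g in self.mapping.items()
        }

    def gene_of(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def genes(self) -> set[str]:
        return {g for g in self.mapping.values() if g is not None}

    def __len__(self) -> int:
        return len(self.mapping)


@dataclasses.dataclass
class TermCollection:
    """term id -> (description, frozenset of gene symbols)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_desc, genes) in self.terms.items():
            if len(genes) == 0:
                raise ValidationError(f"term {tid!r} has an empty gene set")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


@dataclasses.dataclass
class SuperclusterMap:
    """term id -> list of (supercluster, subcluster) assignments.

    A term may carry at most two distinct superclusters, mirroring the
    manual supercluster taxonomy this layer consumes.
    """

    assignments: dict[str, list[tuple[str, str]]]

    def validate(self, terms: TermCollection) -> None:
        for tid, pairs in self.assignments.items():
            if tid not in terms:
                raise ValidationError(f"term {tid!r} not present in the term collection")
            supers = {s for s, _ in pairs}
            if len(supers) > 2:
                raise ValidationError(
                    f"term {tid!r} assigned to {len(supers)} superclusters "
                    f"({sorted(supers)}); at most two are allowed"
                )

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path,
    layout: str = "features_in_rows",
    level: str = "probe",
) -> ExpressionMatrix:
    """Read a TSV intensity table into an :class:`ExpressionMatrix`.

    ``layout`` declares whether features run down the rows (canonical) or
    across the columns.  Every body cell must parse as a number; the first
    offending cell is reported by feature/sample id.
    """
    if layout not in ("features_in_rows", "features_in_columns"):
        raise ValueError(f"unknown layout {layout!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row identifiers: {dup[:5]}")
    if raw.columns.has_duplicates:
        dup = [c for c in raw.columns if list(raw.columns).count(c) > 1]
        raise FormatError(f"{path}: duplicate column identifiers: {sorted(set(dup))[:5]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    bad |= raw.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r}"
            f" (value {raw.iat[r, c]!r})"
        )
    if layout == "features_in_columns":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric, level=level)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature_id")


# ---------------------------------------------------------------------------
# sample sheets and annotation
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: columns ``sample_id``, ``group``, optional ``stage_weeks``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dup}")
    return df.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def validate_samples(matrix: ExpressionMatrix, samples: pd.DataFrame,
                     groups: Iterable[str] | None = None) -> None:
    """Check that every matrix sample is annotated and contrast groups have >= 2 samples."""
    missing = [s for s in matrix.sample_ids if s not in samples.index]
    if missing:
        raise ValidationError(f"samples missing from sample sheet: {missing}")
    if groups is not None:
        counts = samples.loc[matrix.sample_ids, "group"].value_counts()
        for g in groups:
            if counts.get(g, 0) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 samples")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Annotation TSV: columns ``probe_id``, ``gene_symbol`` (symbol may be blank)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation lacks required column {col!r}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"{path}: probe annotated more than once: {dup[:5]}")
    mapping = {
        row.probe_id: (row.gene_symbol if row.gene_symbol else None)
        for row in df.itertuples()
    }
    return ProbeAnnotation(mapping)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        {"probe_id": list(annotation.mapping), "gene_symbol": [
            g if g is not None else "" for g in annotation.mapping.values()
        ]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and the supercluster map
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> TermCollection:
    """Parse a GMT file: one term per line, ``term_id<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; gene order is not
    semantic.  Lines with fewer than three fields and duplicate term ids
    are format errors reported with their line number.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            tid, desc = fields[0], fields[1]
            if tid in terms:
                raise FormatError(f"{path}: line {lineno}: duplicate term id {tid!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: term {tid!r} has no genes")
            terms[tid] = (desc, genes)
    return TermCollection(terms)


def write_gene_sets(terms: TermCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, (desc, genes) in terms.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def read_supercluster_map(path: str | Path, terms: TermCollection) -> SuperclusterMap:
    """Read the term -> (supercluster, subcluster) TSV and validate it.

    Terms absent from the map are allowed (they simply contribute to no
    subcluster); terms present in the map but unknown to the companion
    :class:`TermCollection`, or assigned to more than two superclusters,
    are validation errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("term_id", "supercluster", "subcluster")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: supercluster map lacks column {col!r}")
    assignments: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples():
        pair = (row.supercluster, row.subcluster)
        pairs = assignments.setdefault(row.term_id, [])
        if pair not in pairs:
            pairs.append(pair)
    scmap = SuperclusterMap(assignments)
    scmap.validate(terms)
    return scmap


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (inputs, parameters, seed, counts, warnings)."""
    payload = dict(entries)
    payload.setdefault("package", "thydex")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def log2_transform(values: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(x + offset) for linear-scale input tables (offset defaults to 1)."""
    if (values + offset <= 0).to_numpy().any():
        raise ValidationError("log2 transform undefined: values + offset must be positive")
    return np.log2(values + offset)
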