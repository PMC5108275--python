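"""Data model and I/O for binary dominant-marker matrices.

Dominant markers (ISSR, RAPD, AFLP bands) are scored per individual and
locus as band presence (1) or absence (0).  The central container is
:class:`MarkerMatrix`: a rectangular 0/1 matrix with rows = individuals,
columns = loci, and a population label attached to every individual.
Environment tables (per-population numeric covariates) travel as plain
pandas DataFrames indexed by population label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerDataError",
    "MalformedDataError",
    "DuplicateIdError",
    "FormatError",
    "MarkerMatrix",
    "GroupingScheme",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_env_table",
    "write_env_table",
    "validate",
    "ValidationReport",
]


class MarkerDataError(ValueError):
    """Base class for marker-data validation and format errors."""


class MalformedDataError(MarkerDataError):
    """A cell violates the 0/1 (or numeric) contract."""


class DuplicateIdError(MarkerDataError):
    """An individual or population identifier occurs more than once."""


class FormatError(MarkerDataError):
    """The file layout is not the expected rectangular delimited text."""


@dataclass
class MarkerMatrix:
    """Binary individuals x loci matrix with per-individual population labels.

    Parameters
    ----------
    individual_ids : list of str
        Unique row identifiers, order preserved.
    locus_ids : list of str
        Unique column identifiers, order preserved.
    values : ndarray of shape (n_individuals, n_loci)
        Entries strictly in {0, 1}; no missing cells.
    population_of : dict
        Maps each individual id to exactly one population label.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, L = self.values.shape
        if len(self.individual_ids) != n:
            raise FormatError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.locus_ids) != L:
            raise FormatError(f"{len(self.locus_ids)} locus ids for {L} columns")
        if len(set(self.individual_ids)) != n:
            dup = _first_duplicate(self.individual_ids)
            raise DuplicateIdError(f"duplicate individual id: {dup!r}")
        if len(set(self.locus_ids)) != L:
            dup = _first_duplicate(self.locus_ids)
            raise DuplicateIdError(f"duplicate locus id: {dup!r}")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MalformedDataError(
                f"non-binary cell at individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.int8)
        missing = [i for i in self.individual_ids if i not in self.population_of]
        if missing:
            raise FormatError(f"individuals without population label: {missing[:5]}")

    # -- derived views ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for i in self.individual_ids:
            seen.setdefault(self.population_of[i], None)
        return list(seen)

    def rows_in(self, unit: str) -> np.ndarray:
        """Row indices of a population, or all rows for unit='all'."""
        if unit == "all":
            return np.arange(self.n_individuals)
        idx = np.array(
            [
                k
                for k, ind in enumerate(self.individual_ids)
                if self.population_of[ind] == unit
            ]
        )
        if idx.size == 0:
            raise KeyError(f"unknown population label: {unit!r}")
        return idx

    def submatrix(self, populations: list[str]) -> "MarkerMatrix":
        """Restrict to individuals belonging to the given populations."""
        keep = [
            k
            for k, ind in enumerate(self.individual_ids)
            if self.population_of[ind] in set(populations)
        ]
        ids = [self.individual_ids[k] for k in keep]
        return MarkerMatrix(
            individual_ids=ids,
            locus_ids=list(self.locus_ids),
            values=self.values[keep],
            population_of={i: self.population_of[i] for i in ids},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.locus_ids)
        df.insert(0, "population", [self.population_of[i] for i in self.individual_ids])
        df.insert(0, "id", self.individual_ids)
        return df


@dataclass
class GroupingScheme:
    """Assignment of population labels to higher-level groups."""

    group_of: dict[str, str]
    name: str = "grouping"

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop, grp in self.group_of.items():
            out.setdefault(grp, []).append(pop)
        return out

    def check_covers(self, matrix: MarkerMatrix) -> None:
        missing = [p for p in matrix.populations if p not in self.group_of]
        if missing:
            raise FormatError(
                f"grouping {self.name!r} misses populations: {missing}"
            )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _sniff_sep(path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_marker_matrix(path, dialect: str | None = None) -> MarkerMatrix:
    """Read a delimited 0/1 marker file.

    Layout: header ``id,population,<locus ids...>``; one row per
    individual; cells 0/1.  Comma or tab separated (auto-detected when
    *dialect* is None).
    """
    sep = _sniff_sep(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty marker file: {path}") from exc
    if df.shape[1] < 3:
        raise FormatError(
            f"marker file needs id, population and >=1 locus column; got {df.shape[1]}"
        )
    if df.isna().any().any() or (df == "").any().any():
        raise FormatError(f"ragged or incomplete rows in {path}")
    ids = df.iloc[:, 0].tolist()
    pops = df.iloc[:, 1].tolist()
    locus_ids = [str(c) for c in df.columns[2:]]
    cells = df.iloc[:, 2:].to_numpy()
    values = np.empty(cells.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(cells):
        s = str(cell).strip()
        if s not in ("0", "1"):
            raise MalformedDataError(
                f"non-binary cell at row {ids[i]!r}, column {locus_ids[j]!r}: {s!r}"
            )
        values[i, j] = int(s)
    return MarkerMatrix(
        individual_ids=[str(i) for i in ids],
        locus_ids=locus_ids,
        values=values,
        population_of={str(i): str(p) for i, p in zip(ids, pops)},
    )


def write_marker_matrix(matrix: MarkerMatrix, path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep, index=False)


def read_env_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a per-population environment table.

    Layout: header ``population,<variable names...>``; numeric cells.
    Returns a DataFrame indexed by population label.
    """
    sep = _sniff_sep(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty environment file: {path}") from exc
    if df.shape[1] < 2:
        raise FormatError("environment file needs a label column and >=1 variable")
    labels = df.iloc[:, 0].astype(str)
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise DuplicateIdError(f"duplicate population label: {dup!r}")
    if len(set(df.columns)) != df.shape[1]:
        raise DuplicateIdError("duplicate variable name in header")
    body = df.iloc[:, 1:]
    try:
        values = body.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in environment table: {exc}") from exc
    values.index = pd.Index(labels, name=str(df.columns[0]))
    return values


def write_env_table(env: pd.DataFrame, path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    env.to_csv(path, sep=sep, index=True)


@dataclass
class ValidationReport:
    """Read-only summary of a marker matrix."""

    n_individuals: int
    n_loci: int
    n_populations: int
    monomorphic_absent: list[str] = field(default_factory=list)
    monomorphic_present: list[str] = field(default_factory=list)
    undersized_populations: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_individuals, self.n_loci, self.n_populations)


def validate(matrix: MarkerMatrix) -> ValidationReport:
    """Report globally monomorphic loci and undersized populations.

    Never mutates or rejects the matrix; diversity estimation requires
    >=2 individuals per population, so smaller populations are flagged.
    """
    col_sums = matrix.values.sum(axis=0)
    absent = [l for l, s in zip(matrix.locus_ids, col_sums) if s == 0]
    present = [
        l for l, s in zip(matrix.locus_ids, col_sums) if s == matrix.n_individuals
    ]
    sizes: dict[str, int] = {}
    for ind in matrix.individual_ids:
        pop = matrix.population_of[ind]
        sizes[pop] = sizes.get(pop, 0) + 1
    undersized = [p for p, k in sizes.items() if k < 2]
    return ValidationReport(
        n_individuals=matrix.n_individuals,
        n_loci=matrix.n_loci,
        n_populations=len(sizes),
        monomorphic_absent=absent,
        monomorphic_present=present,
        undersized_populations=undersized,
    )
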