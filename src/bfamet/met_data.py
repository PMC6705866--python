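"""Reading, validation and indexing of multi-environment trial (MET) phenotype data.

A MET dataset is a long-format table of plot-level trait measurements
(one row per genotype x environment x block), possibly unbalanced: whole
genotype-by-environment cells may be missing.  This module validates such
tables, builds stable genotype/environment index maps, and constructs the
incidence (design) matrices that distribute the factor-analytic model
effects onto observations:

* ``X1`` (n x c): environment-block cell means coding for the fixed effects,
  one column per occurring cell (no global intercept, full rank whenever
  every cell has at least one record);
* ``X2`` (n x p): environment indicators, used to spread the environment
  loadings;
* ``Zf`` (n x m): genotype indicators, used to spread the factor scores;
* ``Z``  (n x mp): genotype-by-environment cell indicators for the specific
  effects, columns ordered genotype-major (cell (i, j) -> column (i-1)*p + j-1,
  matching a prior covariance of the form I_m (x) Psi).

Indices are 1-based in documentation and error messages; internally the
module uses 0-based positions, which are never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "METFormatError",
    "METValidationError",
    "METParseError",
    "METDataset",
    "DesignMatrices",
    "read_met_csv",
    "build_design_matrices",
]


class METFormatError(ValueError):
    """The input table is structurally unusable (e.g., a mapped column is absent)."""


class METValidationError(ValueError):
    """The table violates a dataset invariant (duplicates, orphan levels...)."""


class METParseError(ValueError):
    """A value could not be parsed as a number."""


# default column names auto-detected in input CSV files
_DEFAULT_COLUMNS = {
    "genotype": ("gen", "genotype", "gen_id", "g"),
    "environment": ("env", "environment", "env_id", "e"),
    "block": ("rep", "block", "blk", "r"),
    "value": ("y", "value", "yield", "trait"),
}


@dataclass(frozen=True)
class METDataset:
    """Validated long-format MET phenotype data with stable index maps.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``genotype``, ``environment``, ``block`` (strings) and
        ``value`` (float), in input row order.
    genotypes, environments : list of str
        Level labels in order of first appearance; positions define the
        1..m / 1..p index maps.
    cell_table : ndarray of bool, shape (m, p)
        ``True`` where the genotype x environment cell has at least one record.
    """

    records: pd.DataFrame
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)
    cell_table: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.records
        required = {"genotype", "environment", "block", "value"}
        missing = required - set(df.columns)
        if missing:
            raise METFormatError(f"records missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise METValidationError("non-finite trait values present")
        dup = df.duplicated(subset=["genotype", "environment", "block"])
        if dup.any():
            row = df[dup].iloc[0]
            raise METValidationError(
                "duplicate (genotype, environment, block) triple: "
                f"({row['genotype']}, {row['environment']}, {row['block']})"
            )
        gens = list(dict.fromkeys(df["genotype"]))
        envs = list(dict.fromkeys(df["environment"]))
        object.__setattr__(self, "genotypes", gens)
        object.__setattr__(self, "environments", envs)
        gi = df["genotype"].map({g: i for i, g in enumerate(gens)}).to_numpy()
        ei = df["environment"].map({e: j for j, e in enumerate(envs)}).to_numpy()
        cells = np.zeros((len(gens), len(envs)), dtype=bool)
        cells[gi, ei] = True
        object.__setattr__(self, "cell_table", cells)
        if not cells.any(axis=1).all():  # pragma: no cover - unreachable by construction
            raise METValidationError("genotype with zero records")

    # -- shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m(self) -> int:
        return len(self.genotypes)

    @property
    def p(self) -> int:
        return len(self.environments)

    @property
    def q(self) -> int:
        """Maximum number of blocks within any environment."""
        return int(
            self.records.groupby("environment", sort=False)["block"].nunique().max()
        )

    def _cached(self, name: str, build) -> np.ndarray:
        # frozen dataclass: memoize derived arrays the sampler hits per scan
        value = self.__dict__.get(name)
        if value is None:
            value = build()
            object.__setattr__(self, name, value)
        return value

    # -- integer index views (0-based, internal convention) --------------
    @property
    def genotype_index(self) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotypes)}
        return self._cached(
            "_gen_idx",
            lambda: self.records["genotype"].map(lookup).to_numpy(dtype=np.int64),
        )

    @property
    def environment_index(self) -> np.ndarray:
        lookup = {e: j for j, e in enumerate(self.environments)}
        return self._cached(
            "_env_idx",
            lambda: self.records["environment"].map(lookup).to_numpy(dtype=np.int64),
        )

    @property
    def y(self) -> np.ndarray:
        return self._cached(
            "_y", lambda: self.records["value"].to_numpy(dtype=float)
        )

    def records_per_environment(self) -> np.ndarray:
        """n_j: number of records in each environment (length p)."""
        return self._cached(
            "_n_per_env",
            lambda: np.bincount(self.environment_index, minlength=self.p),
        )

    def genotypes_per_environment(self) -> np.ndarray:
        """m_j: number of observed genotype cells in each environment."""
        return self.cell_table.sum(axis=0).astype(np.int64)

    def summary(self) -> dict:
        """Counts and per-environment missingness, JSON-serializable."""
        n_per_env = self.records_per_environment()
        return {
            "n": self.n,
            "m": self.m,
            "p": self.p,
            "q": self.q,
            "environments": {
                env: {
                    "records": int(n_per_env[j]),
                    "missing_cells": int(self.m - self.cell_table[:, j].sum()),
                }
                for j, env in enumerate(self.environments)
            },
        }

    def subset(self, keep: np.ndarray) -> "METDataset":
        """Dataset restricted to the records where ``keep`` is True.

        Raises
        ------
        METValidationError
            If the restriction leaves a genotype or environment of this
            dataset with zero records (estimability would be lost).
        """
        out = METDataset(self.records.loc[np.asarray(keep)].reset_index(drop=True))
        lost_g = set(self.genotypes) - set(out.genotypes)
        lost_e = set(self.environments) - set(out.environments)
        if lost_g:
            raise METValidationError(
                f"genotype with zero records after filtering: {sorted(lost_g)}"
            )
        if lost_e:
            raise METValidationError(
                f"environment with zero records after filtering: {sorted(lost_e)}"
            )
        return out

    def drop_cells(self, cells: list[tuple[str, str]]) -> "METDataset":
        """Remove all replicates of the named genotype x environment cells."""
        forbidden = set(cells)
        mask = [
            (g, e) not in forbidden
            for g, e in zip(self.records["genotype"], self.records["environment"])
        ]
        return self.subset(np.asarray(mask))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class DesignMatrices:
    """Sparse incidence matrices of the summation-form FA model.

    ``cell_labels`` names the environment-block columns of ``X1``; the
    convenience index arrays (0-based positions into the matrix columns)
    carry the same information row-wise and are what the sampler uses.
    """

    X1: sparse.csr_matrix  # n x c environment-block cells
    X2: sparse.csr_matrix  # n x p environments
    Z: sparse.csr_matrix  # n x mp genotype-by-environment cells
    Zf: sparse.csr_matrix  # n x m genotypes
    cell_labels: list[tuple[str, str]]
    cell_index: np.ndarray  # n, column of X1
    env_index: np.ndarray  # n, column of X2
    ge_index: np.ndarray  # n, column of Z
    gen_index: np.ndarray  # n, column of Zf

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)


def _indicator(rows: int, cols: np.ndarray, n_cols: int) -> sparse.csr_matrix:
    data = np.ones(rows)
    return sparse.csr_matrix(
        (data, (np.arange(rows), cols)), shape=(rows, n_cols)
    )


def build_design_matrices(data: METDataset) -> DesignMatrices:
    """Construct the four incidence matrices for a validated dataset.

    Row i of every matrix corresponds to record i; each row holds a single 1.
    ``X1`` has one column per occurring environment-block cell so that the
    fixed-effect vector is estimable even in incomplete block designs.
    """
    df = data.records
    env_idx = data.environment_index
    gen_idx = data.genotype_index

    cell_keys = list(zip(df["environment"], df["block"]))
    cell_labels = list(dict.fromkeys(cell_keys))
    cell_pos = {c: i for i, c in enumerate(cell_labels)}
    cell_idx = np.array([cell_pos[c] for c in cell_keys], dtype=np.int64)

    ge_idx = gen_idx * data.p + env_idx

    return DesignMatrices(
        X1=_indicator(data.n, cell_idx, len(cell_labels)),
        X2=_indicator(data.n, env_idx, data.p),
        Z=_indicator(data.n, ge_idx, data.m * data.p),
        Zf=_indicator(data.n, gen_idx, data.m),
        cell_labels=cell_labels,
        cell_index=cell_idx,
        env_index=env_idx,
        ge_index=ge_idx,
        gen_index=gen_idx,
    )


def read_met_csv(
    path,
    genotype: str | None = None,
    environment: str | None = None,
    block: str | None = None,
    value: str | None = None,
) -> METDataset:
    """Read a long-format MET phenotype CSV into a validated :class:`METDataset`.

    Columns named ``gen``/``env``/``rep`` (or ``block``)/``y`` are auto-detected
    (case-insensitive); pass explicit names for anything else.  Input row
    order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    lower = {c.lower(): c for c in df.columns}

    def resolve(role: str, explicit: str | None) -> str:
        if explicit is not None:
            if explicit not in df.columns:
                raise METFormatError(f"column {explicit!r} (for {role}) not in file")
            return explicit
        for candidate in _DEFAULT_COLUMNS[role]:
            if candidate in lower:
                return lower[candidate]
        raise METFormatError(
            f"could not auto-detect a {role} column; "
            f"tried {_DEFAULT_COLUMNS[role]}, found {list(df.columns)}"
        )

    cols = {
        "genotype": resolve("genotype", genotype),
        "environment": resolve("environment", environment),
        "block": resolve("block", block),
        "value": resolve("value", value),
    }
    out = pd.DataFrame(
        {role: df[name].astype(str) for role, name in cols.items() if role != "value"}
    )
    raw = pd.to_numeric(df[cols["value"]], errors="coerce")
    bad = raw.isna() & df[cols["value"]].notna()
    if bad.any():
        rownum = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise METParseError(
            f"non-numeric value {df[cols['value']][bad].iloc[0]!r} "
            f"in column {cols['value']!r} at file row {rownum}"
        )
    if raw.isna().any():
        raise METValidationError("missing trait values present")
    out["value"] = raw.astype(float)
    return METDataset(out.reset_index(drop=True))
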