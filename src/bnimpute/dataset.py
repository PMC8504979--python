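"""Typed mixed discrete/continuous datasets with missing-value awareness.

A :class:`MixedDataset` wraps a pandas DataFrame of individuals (rows) by
variables (columns).  Each variable carries a :class:`VariableSpec` declaring
whether it is discrete or continuous and whether it is a *genetic* variable
(a causal anchor: fixed at conception, so edges may only point out of it).
Missing entries are tracked through an explicit boolean ``observed_mask``.

Row identifiers are 0-based internally; user-facing reports (provenance
logs, error messages) use 1-based row numbers.  This convention is set here
once and reused by every other module.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "MixedDataset",
    "ConfigurationError",
    "EmptyDatasetError",
    "read_dataset",
    "read_variable_specs",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent user configuration (constraints, specs, files)."""


class EmptyDatasetError(ValueError):
    """Raised when an operation requires rows but the dataset has none."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single variable.

    Parameters
    ----------
    name : str
        Unique variable name.
    kind : {"discrete", "continuous"}
        Distributional family: multinomial or (conditional) Gaussian.
    genetic : bool
        Causal-anchor flag.  Genetic variables admit no incoming edges.
        Allowed on either kind, since SNPs may be coded as continuous
        allele dosages.
    levels : tuple of str
        Ordered category labels (discrete variables only).
    """

    name: str
    kind: str
    genetic: bool = False
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ConfigurationError(
                f"variable {self.name!r}: kind must be 'discrete' or "
                f"'continuous', got {self.kind!r}"
            )
        if self.kind == "continuous" and self.levels:
            raise ConfigurationError(
                f"variable {self.name!r}: continuous variables take no levels"
            )
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class MixedDataset:
    """An individuals-by-variables table with explicit missingness.

    Parameters
    ----------
    variables : sequence of VariableSpec
        One spec per column, order matching ``frame`` columns.
    frame : pandas.DataFrame
        The data.  Continuous columns are floats with NaN for missing;
        discrete columns hold string labels with NaN/None for missing.
        The index carries the (0-based) original row identifiers and is
        preserved by row subsetting.

    Notes
    -----
    Discrete levels observed in the data but absent from the spec are
    appended to the spec with a warning, so partially specified metadata
    does not abort an analysis.
    """

    def __init__(self, variables, frame: pd.DataFrame):
        variables = list(variables)
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate variable names in dataset")
        if list(frame.columns) != names:
            raise ConfigurationError(
                "frame columns do not match variable specs: "
                f"{list(frame.columns)} vs {names}"
            )
        frame = frame.copy()
        fixed = []
        for v in variables:
            col = frame[v.name]
            if v.is_continuous:
                try:
                    frame[v.name] = pd.to_numeric(col, errors="raise")
                except (ValueError, TypeError) as exc:
                    raise ConfigurationError(
                        f"column {v.name!r} declared continuous but holds "
                        f"non-numeric values"
                    ) from exc
                fixed.append(v)
            else:
                labels = col.dropna().astype(str)
                seen = list(dict.fromkeys(labels))
                extra = [l for l in seen if l not in v.levels]
                levels = v.levels + tuple(extra)
                # warn only on *partial* declarations; a spec with no levels
                # at all (e.g. from a sidecar file) takes them from the data
                if extra and v.levels:
                    warnings.warn(
                        f"variable {v.name!r}: levels {extra} observed in data "
                        f"but not declared; appending",
                        stacklevel=2,
                    )
                if len(levels) < 2:
                    raise ConfigurationError(
                        f"discrete variable {v.name!r} has fewer than 2 levels"
                    )
                frame[v.name] = col.where(col.isna(), col.astype(str))
                fixed.append(VariableSpec(v.name, v.kind, v.genetic, levels))
        self.variables: list[VariableSpec] = fixed
        self.frame: pd.DataFrame = frame
        self._by_name = {v.name: v for v in self.variables}
        self._codes = None
        self._mask = None

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of individuals."""
        return len(self.frame)

    @property
    def p(self) -> int:
        """Number of variables."""
        return len(self.variables)

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    def spec(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean n x p array, True where the value is observed.

        Cached: datasets are treated as immutable (subsetting and
        imputation always build new objects)."""
        if self._mask is None:
            self._mask = self.frame.notna().to_numpy()
            self._mask.setflags(write=False)
        return self._mask

    @property
    def row_ids(self) -> np.ndarray:
        """Original (0-based) row identifiers of the current rows."""
        return self.frame.index.to_numpy()

    # -- numeric view --------------------------------------------------------

    def numeric_values(self) -> np.ndarray:
        """n x p float matrix: continuous values, discrete level codes.

        Missing entries are NaN.  Level codes follow the declared level
        order of each spec.  Cached; treat as read-only.
        """
        if self._codes is None:
            cols = []
            for v in self.variables:
                col = self.frame[v.name]
                if v.is_continuous:
                    cols.append(col.to_numpy(dtype=float))
                else:
                    cat = pd.Categorical(col, categories=list(v.levels))
                    codes = cat.codes.astype(float)
                    codes[codes < 0] = np.nan
                    cols.append(codes)
            self._codes = np.column_stack(cols) if cols else np.empty((self.n, 0))
            self._codes.setflags(write=False)
        return self._codes

    # -- subsetting ----------------------------------------------------------

    def take_rows(self, positions) -> "MixedDataset":
        """Row subset by current positional indices (order preserved)."""
        return MixedDataset(self.variables, self.frame.iloc[np.asarray(positions)])

    def select(self, names) -> "MixedDataset":
        """Column subset, preserving row identity."""
        specs = [self._by_name[n] for n in names]
        return MixedDataset(specs, self.frame[list(names)])

    def complete_rows(self) -> "MixedDataset":
        """Rows where every variable is observed (the "Reduced" strategy).

        Raises
        ------
        EmptyDatasetError
            If no row is fully observed; downstream fitting must refuse
            rather than silently work with nothing.
        """
        keep = self.frame.notna().all(axis=1)
        if not keep.any():
            raise EmptyDatasetError("no rows with all variables observed")
        return MixedDataset(self.variables, self.frame.loc[keep])

    def n_complete(self) -> int:
        return int(self.frame.notna().all(axis=1).sum())

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.variables, self.frame)

    def __repr__(self):
        kinds = sum(v.is_discrete for v in self.variables)
        return (
            f"<MixedDataset n={self.n} p={self.p} "
            f"({kinds} discrete, {self.p - kinds} continuous)>"
        )

    # -- i/o -----------------------------------------------------------------

    def to_file(self, path, sep="\t", missing="NA"):
        self.frame.to_csv(path, sep=sep, index=False, na_rep=missing)


def read_variable_specs(path) -> list:
    """Read a variable sidecar: ``name<TAB>kind[<TAB>genetic]`` per line.

    ``kind`` is ``d``/``discrete`` or ``c``/``continuous``; the optional
    third token ``genetic`` flags a causal anchor.
    """
    specs = []
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ConfigurationError(
                f"variable file line {lineno}: expected 'name kind [genetic]'"
            )
        name, kind = parts[0], parts[1].lower()
        kind = {"d": "discrete", "c": "continuous"}.get(kind, kind)
        genetic = len(parts) > 2 and parts[2].lower() == "genetic"
        specs.append(VariableSpec(name, kind, genetic))
    if not specs:
        raise ConfigurationError("variable file declares no variables")
    return specs


def read_dataset(data_path, variables_path, sep=None, missing="NA") -> MixedDataset:
    """Read a delimited data file plus its variable sidecar.

    Tab is the default delimiter; comma is accepted (``sep=','`` or
    sniffed from the header when ``sep`` is None).
    """
    specs = read_variable_specs(variables_path)
    if sep is None:
        with open(data_path) as fh:
            header = fh.readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    frame = pd.read_csv(
        data_path, sep=sep, na_values=[missing], keep_default_na=False, dtype=object
    )
    expected = [s.name for s in specs]
    if list(frame.columns) != expected:
        raise ConfigurationError(
            f"data columns {list(frame.columns)} do not match variable "
            f"sidecar {expected}"
        )
    return MixedDataset(specs, frame)
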