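"""Core data containers and CSV input/output.

The package works on three primitive objects: a :class:`DescriptorMatrix`
(compounds x named numeric molecular descriptors), a :class:`ResponseVector`
(one toxicity endpoint, in -log10 molar units such as pEC50), and an optional
:class:`SplitSpec` assigning compounds to the training or test set.  A
:class:`Dataset` joins the three on compound identifiers.  Observed/predicted
value pairs travel as :class:`PairedPredictions`.

All files are plain CSV (UTF-8, "." decimal separator).  Empty cells, ``NA``
and ``NaN`` are read as missing values.  Compound identity is the verbatim
string in the first column, never a positional index.

The package also ships a benchmark dataset: observed and model-calculated
toxicity values for 50 drinking-water disinfection byproducts (DBPs) in five
bioassays (X-Microtox, GSH+, GSH-, DNA+, DNA-), with their train/test
assignments; see :func:`load_benchmark_pairs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, SchemaError

NA_STRINGS = ("", "NA", "NaN", "nan", "-")

#: endpoints of the bundled DBP toxicity benchmark
BENCHMARK_ENDPOINTS = ("X-Microtox", "GSH+", "GSH-", "DNA+", "DNA-")

_FIXTURE_FILES = {
    "X-Microtox": "x_microtox.csv",
    "GSH+": "gsh_plus.csv",
    "GSH-": "gsh_minus.csv",
    "DNA+": "dna_plus.csv",
    "DNA-": "dna_minus.csv",
}


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise FormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors numeric matrix with row/column names.

    Wraps a :class:`pandas.DataFrame` whose index holds compound identifiers
    (strings) and whose columns hold descriptor names.  Entries may be NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        _check_unique(self.frame.index, "compound IDs")
        _check_unique(self.frame.columns, "descriptor names")
        self.frame = self.frame.astype(float)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def select(self, names: Iterable[str]) -> "DescriptorMatrix":
        names = list(names)
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise SchemaError(f"descriptor columns not present: {missing}")
        return DescriptorMatrix(self.frame[names])

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorMatrix":
        return read_descriptor_matrix(path)

    def to_csv(self, path: str | Path) -> None:
        write_descriptor_matrix(self, path)


@dataclass
class ResponseVector:
    """One endpoint's response values, indexed by compound ID.

    Values are negative log10 molar effect concentrations (pEC50 for the
    Microtox assay, pEC_IR1.5 for the E. coli assays) or any user endpoint.
    Missing responses are NaN and are excluded from every fit.
    """

    series: pd.Series
    endpoint: str = "response"

    def __post_init__(self) -> None:
        self.series = self.series.copy()
        self.series.index = self.series.index.astype(str)
        _check_unique(self.series.index, "compound IDs")
        self.series = self.series.astype(float)
        self.series.name = self.endpoint

    @property
    def compound_ids(self) -> list[str]:
        return list(self.series.index)

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()

    def dropna(self) -> "ResponseVector":
        return ResponseVector(self.series.dropna(), self.endpoint)

    @classmethod
    def read_csv(cls, path: str | Path, endpoint: str | None = None) -> "ResponseVector":
        return read_response(path, endpoint)


@dataclass
class SplitSpec:
    """Assignment of compound IDs to the training or test set."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values()} - {"train", "test"}
        if bad:
            raise FormatError(f"split labels must be 'train'/'test', got {sorted(bad)}")
        self.assignment = {str(k): v for k, v in self.assignment.items()}

    @property
    def train_ids(self) -> list[str]:
        return [k for k, v in self.assignment.items() if v == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [k for k, v in self.assignment.items() if v == "test"]

    @classmethod
    def read_csv(cls, path: str | Path) -> "SplitSpec":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise FormatError("split CSV needs two columns: compound ID, train/test")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"id": list(self.assignment), "set": list(self.assignment.values())}
        ).to_csv(path, index=False)


@dataclass
class Dataset:
    """Descriptor matrix inner-joined to one endpoint's response.

    Compounds with a missing response are dropped at construction; the
    remaining compound IDs are the intersection of matrix and response IDs,
    in matrix order.  The optional split must only reference those IDs.
    """

    descriptors: DescriptorMatrix
    response: ResponseVector
    split: SplitSpec | None = None

    def __post_init__(self) -> None:
        resp = self.response.dropna()
        ids = [i for i in self.descriptors.compound_ids if i in set(resp.compound_ids)]
        if not ids:
            raise FormatError("no compounds shared between descriptors and response")
        self.descriptors = DescriptorMatrix(self.descriptors.frame.loc[ids])
        self.response = ResponseVector(resp.series.loc[ids], resp.endpoint)
        if self.split is not None:
            unknown = set(self.split.assignment) - set(ids)
            if unknown:
                raise FormatError(f"split references unknown compounds: {sorted(unknown)}")

    @property
    def compound_ids(self) -> list[str]:
        return self.descriptors.compound_ids

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def subset(self, which: str) -> "Dataset":
        """Return the training or test part (``which`` in {'train','test'})."""
        if self.split is None:
            raise SchemaError("dataset has no split")
        ids = [i for i in self.compound_ids if self.split.assignment.get(i) == which]
        if not ids:
            raise FormatError(f"{which} set is empty")
        return Dataset(
            DescriptorMatrix(self.descriptors.frame.loc[ids]),
            ResponseVector(self.response.series.loc[ids], self.response.endpoint),
        )


@dataclass
class PairedPredictions:
    """Observed/predicted response pairs with per-compound subset labels."""

    compound_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    subset: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.compound_ids = [str(i) for i in self.compound_ids]
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        n = len(self.compound_ids)
        if not self.subset:
            self.subset = ["train"] * n
        if not (len(self.observed) == len(self.predicted) == len(self.subset) == n):
            raise FormatError("paired predictions: unequal field lengths")
        if n < 1:
            raise FormatError("paired predictions cannot be empty")
        if np.isnan(self.observed).any() or np.isnan(self.predicted).any():
            raise FormatError("paired predictions must not contain missing values")

    def __len__(self) -> int:
        return len(self.compound_ids)

    def part(self, which: str) -> "PairedPredictions":
        """Pairs whose subset label equals ``which`` ('train' or 'test')."""
        idx = [i for i, s in enumerate(self.subset) if s == which]
        return PairedPredictions(
            [self.compound_ids[i] for i in idx],
            self.observed[idx],
            self.predicted[idx],
            [which] * len(idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.compound_ids,
                "observed": self.observed,
                "predicted": self.predicted,
                "set": self.subset,
            }
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a compounds-x-descriptors CSV.

    First column: compound IDs (verbatim strings).  Header row: descriptor
    names.  Cells must be numeric or missing (empty/NA/NaN).  A non-numeric
    non-missing cell raises :class:`ParseError` naming the row and column.
    """
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    _check_unique(header[1:], "descriptor names")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError("descriptor CSV needs an ID column plus >= 1 descriptor")
    ids = raw.iloc[:, 0].tolist()
    _check_unique(ids, "compound IDs")
    body = raw.iloc[:, 1:]
    numeric = {}
    for col in body.columns:
        cleaned = body[col].str.strip().replace(list(NA_STRINGS), np.nan)
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.isna() & cleaned.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {body[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        numeric[col] = converted.to_numpy()
    frame = pd.DataFrame(numeric, index=ids)
    return DescriptorMatrix(frame)


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path) -> None:
    """Write a descriptor matrix CSV; NaN becomes an empty cell."""
    out = matrix.frame.copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, index=False, na_rep="")


def read_response(path: str | Path, endpoint: str | None = None) -> ResponseVector:
    """Read a response CSV with columns: compound ID, endpoint name, value.

    A two-column file (ID, value) is also accepted; the endpoint then
    defaults to the value column's header.  With a three-column file and
    several endpoints present, ``endpoint`` selects which one to load.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] == 2:
        ids, vals = raw.iloc[:, 0], raw.iloc[:, 1]
        name = endpoint or str(raw.columns[1])
    elif raw.shape[1] >= 3:
        eps = raw.iloc[:, 1]
        if endpoint is None:
            uniq = eps.unique()
            if len(uniq) > 1:
                raise FormatError(
                    f"file holds several endpoints {list(uniq)}; pass endpoint="
                )
            endpoint = str(uniq[0])
        keep = eps == endpoint
        if not keep.any():
            raise LookupError(f"endpoint {endpoint!r} not present in {path}")
        ids, vals = raw.iloc[:, 0][keep], raw.iloc[:, 2][keep]
        name = endpoint
    else:
        raise FormatError("response CSV needs (id, value) or (id, endpoint, value)")
    cleaned = vals.str.strip().replace(list(NA_STRINGS), np.nan)
    converted = pd.to_numeric(cleaned, errors="coerce")
    bad = converted.isna() & cleaned.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric response {vals.iloc[row]!r} at data row {row + 1}")
    return ResponseVector(pd.Series(converted.to_numpy(), index=ids.tolist()), name)


def write_response(response: ResponseVector, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": response.compound_ids,
            "endpoint": response.endpoint,
            "value": response.values,
        }
    ).to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Bundled DBP toxicity benchmark
# ---------------------------------------------------------------------------

def load_benchmark_pairs(endpoint: str) -> PairedPredictions:
    """Load observed/calculated pairs for one bundled DBP benchmark endpoint.

    Returns the published observed and model-calculated toxicity values
    (4-decimal precision) for the compounds measured in that bioassay,
    with each pair labelled 'train' or 'test'.  Compounds without a value
    for the endpoint are absent from the file.
    """
    if endpoint not in _FIXTURE_FILES:
        raise LookupError(
            f"unknown endpoint {endpoint!r}; choose from {list(_FIXTURE_FILES)}"
        )
    ref = resources.files("qsarval.fixtures") / _FIXTURE_FILES[endpoint]
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, dtype={"id": str})
    return PairedPredictions(
        df["id"].tolist(),
        df["observed"].to_numpy(float),
        df["calculated"].to_numpy(float),
        df["set"].tolist(),
    )
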