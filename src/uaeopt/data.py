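"""In-study dataset and file I/O.

The complete campaign — a 15-run factorial subset over extraction time,
temperature and sample-to-solvent ratio, thirteen bioactivity responses
measured in triplicate, and the three published MLP surrogates — is bundled
as plain-text fixtures and exposed through the same readers used for
user-supplied CSV files.

Response units follow the assay conventions: TPC mg GAE/g, TFC mg RE/g,
DPPH/ABTS/CUPRAC/FRAP mg TE/g, MC mg EDTAE/g, PM mmol TE/g, AChE/BChE
mg GALAE/g, tyrosinase mg KAE/g, alpha-amylase/alpha-glucosidase
mmol ACAE/g.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mlp import MLPParameters

__all__ = [
    "ExtractionDesign", "ResponseMatrix", "PublishedWeights", "ParseError",
    "RESPONSE_NAMES", "FACTOR_NAMES", "response_units",
    "load_design", "load_responses", "load_published_model",
    "load_published_fit_table", "load_printed_reference",
    "write_design", "write_responses", "design_matrix",
]

FACTOR_NAMES = ("time", "temperature", "ratio")

RESPONSE_NAMES = (
    "TPC", "TFC", "DPPH", "ABTS", "CUPRAC", "FRAP", "MC", "PM",
    "AChE", "BChE", "Tyrosinase", "alpha-amylase", "alpha-glucosidase",
)

PUBLISHED_MODEL_IDS = ("ANN1", "ANN2", "ANN3")


class ParseError(ValueError):
    """A design/response table failed to parse or validate."""


@dataclass(frozen=True)
class ExtractionDesign:
    """One extraction run: time [min], temperature [degC], ratio [mL/g].

    The ratio is the solvent volume per gram of material, i.e. the
    denominator R of a "1:R g/mL" sample-to-solvent ratio.
    """

    sample_id: int
    time: float
    temperature: float
    ratio: float

    def __post_init__(self):
        for name in FACTOR_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ParseError(
                    f"sample {self.sample_id}: {name} must be a positive "
                    f"number, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.time, self.temperature, self.ratio], float)


def design_matrix(designs: list[ExtractionDesign]) -> np.ndarray:
    """Stack runs into the (n, 3) factor matrix consumed by the models."""
    return np.array([d.as_array() for d in designs])


@dataclass
class ResponseMatrix:
    """Samples x responses table of assay means and replicate SDs."""

    sample_ids: list[int]
    response_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    units: dict[str, str] = field(default_factory=dict)
    n_replicates: int = 3

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n, m = len(self.sample_ids), len(self.response_names)
        if len(set(self.sample_ids)) != n:
            raise ParseError("duplicate sample_id in response table")
        if len(set(self.response_names)) != m:
            raise ParseError("duplicate response name in response table")
        if n == 0 or m == 0:
            raise ParseError("response table must contain at least one "
                             "sample and one response")
        if self.means.shape != (n, m) or self.sds.shape != (n, m):
            raise ParseError(
                f"shape mismatch: expected {(n, m)}, got means "
                f"{self.means.shape}, sds {self.sds.shape}")
        if not np.isfinite(self.means).all():
            raise ParseError("response means contain missing or non-finite "
                             "values")
        if (self.sds < 0).any():
            i, j = np.argwhere(self.sds < 0)[0]
            raise ParseError(
                f"negative SD for sample {self.sample_ids[i]}, response "
                f"{self.response_names[j]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, name: str) -> np.ndarray:
        return self.means[:, self.response_names.index(name)]

    def subset(self, names: list[str]) -> "ResponseMatrix":
        idx = [self.response_names.index(n) for n in names]
        return ResponseMatrix(
            sample_ids=list(self.sample_ids), response_names=list(names),
            means=self.means[:, idx], sds=self.sds[:, idx],
            units={n: self.units.get(n, "") for n in names},
            n_replicates=self.n_replicates)

    def to_frame(self, with_sd: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(self.means, columns=self.response_names,
                             index=pd.Index(self.sample_ids,
                                            name="sample_id"))
        if with_sd:
            for j, name in enumerate(self.response_names):
                frame[f"{name}_sd"] = self.sds[:, j]
        return frame


@dataclass
class PublishedWeights:
    """One published surrogate: architecture, parameters and fit summary."""

    model_id: str
    parameters: MLPParameters
    input_names: list[str]
    output_names: list[str]
    summary: dict


def _fixture_path(name: str) -> Path:
    return resources.files("uaeopt.fixtures").joinpath(name)


def response_units() -> dict[str, str]:
    """The bundled response-name -> unit dictionary."""
    with _fixture_path("units.json").open() as fh:
        return json.load(fh)


def _read_csv(source) -> pd.DataFrame:
    try:
        return pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas message wrapped
        raise ParseError(f"could not read {source}: {exc}") from exc


def load_design(source: str | Path = "paper") -> list[ExtractionDesign]:
    """Load an extraction design from the bundled fixture or a CSV file.

    ``source="paper"`` returns the 15-run in-study design; any other value
    is treated as a path to a CSV with columns sample_id (optional), time,
    temperature and ratio.
    """
    if source == "paper":
        source = _fixture_path("design.csv")
    table = _read_csv(source)
    for col in FACTOR_NAMES:
        if col not in table.columns:
            raise ParseError(f"design table is missing column {col!r}")
    if "sample_id" not in table.columns:
        table = table.copy()
        table["sample_id"] = np.arange(1, len(table) + 1)
    if table["sample_id"].duplicated().any():
        dup = table["sample_id"][table["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate sample_id {dup}")
    designs = []
    for row_number, row in enumerate(table.itertuples(index=False), start=1):
        try:
            designs.append(ExtractionDesign(
                sample_id=int(row.sample_id), time=float(row.time),
                temperature=float(row.temperature), ratio=float(row.ratio)))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"design row {row_number}: {exc}") from exc
    return designs


def load_responses(source: str | Path = "paper") -> ResponseMatrix:
    """Load a response table (means and SDs) from fixture or CSV.

    The CSV schema is one ``sample_id`` column followed by pairs
    ``<response>`` / ``<response>_sd``; a missing SD column is taken as 0.
    Responses not in the bundled unit dictionary are carried unitless with
    a warning.
    """
    if source == "paper":
        source = _fixture_path("responses.csv")
    table = _read_csv(source)
    if "sample_id" not in table.columns:
        raise ParseError("response table is missing column 'sample_id'")
    names = [c for c in table.columns
             if c != "sample_id" and not c.endswith("_sd")]
    if not names:
        raise ParseError("response table contains no response columns")
    units = response_units()
    unknown = [n for n in names if n not in units]
    if unknown:
        warnings.warn(f"unknown response name(s) {unknown}; carried "
                      "unitless", stacklevel=2)
    means = np.empty((len(table), len(names)))
    sds = np.zeros_like(means)
    for j, name in enumerate(names):
        means[:, j] = pd.to_numeric(table[name], errors="raise")
        sd_col = f"{name}_sd"
        if sd_col in table.columns:
            sds[:, j] = pd.to_numeric(table[sd_col], errors="raise")
    return ResponseMatrix(
        sample_ids=[int(s) for s in table["sample_id"]],
        response_names=names, means=means, sds=sds,
        units={n: units.get(n, "") for n in names})


def load_published_model(model_id: str) -> PublishedWeights:
    """Load one of the published surrogates (ANN1, ANN2 or ANN3).

    ANN1 is an MLP 3-9-2 (TPC, TFC; tanh/identity), ANN2 an MLP 3-10-6
    (antioxidant assays; tanh/tanh) and ANN3 an MLP 3-10-5 (enzyme
    inhibition; logistic/identity).
    """
    if model_id not in PUBLISHED_MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; valid ids: "
                         f"{', '.join(PUBLISHED_MODEL_IDS)}")
    with _fixture_path(model_id.lower() + ".json").open() as fh:
        doc = json.load(fh)
    params = MLPParameters(
        W1=np.asarray(doc["W1"], dtype=float),
        B1=np.asarray(doc["B1"], dtype=float),
        W2=np.asarray(doc["W2"], dtype=float),
        B2=np.asarray(doc["B2"], dtype=float),
        hidden_activation=doc["hidden_activation"],
        output_activation=doc["output_activation"])
    n_in, n_hidden, n_out = doc["architecture"]
    if params.W1.shape != (n_hidden, n_in) or \
            params.W2.shape != (n_out, n_hidden):
        raise ParseError(f"{model_id}: stored shapes do not match the "
                         f"declared {n_in}-{n_hidden}-{n_out} architecture")
    return PublishedWeights(
        model_id=doc["model_id"], parameters=params,
        input_names=doc["input_names"], output_names=doc["output_names"],
        summary=doc["summary"])


def load_published_fit_table() -> pd.DataFrame:
    """The published per-response goodness-of-fit statistics."""
    return pd.read_csv(_fixture_path("published_fit_table.csv"),
                       index_col="response")


def load_printed_reference() -> dict:
    """Reference values printed in the study, used for comparison tables."""
    with _fixture_path("printed_reference.json").open() as fh:
        return json.load(fh)


def write_design(designs: list[ExtractionDesign], path: str | Path) -> Path:
    if not designs:
        raise ValueError("cannot write an empty design")
    path = Path(path)
    frame = pd.DataFrame(
        {"sample_id": [d.sample_id for d in designs],
         "time": [d.time for d in designs],
         "temperature": [d.temperature for d in designs],
         "ratio": [d.ratio for d in designs]})
    frame.to_csv(path, index=False)
    return path


def write_responses(responses: ResponseMatrix, path: str | Path) -> Path:
    if responses.n_samples == 0:
        raise ValueError("cannot write an empty response table")
    path = Path(path)
    frame = pd.DataFrame({"sample_id": responses.sample_ids})
    for j, name in enumerate(responses.response_names):
        frame[name] = responses.means[:, j]
        frame[f"{name}_sd"] = responses.sds[:, j]
    frame.to_csv(path, index=False)
    return path
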