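"""Quantification tables and regulator networks: in-memory model and TSV round trip.

The central exchange object is :class:`QuantTable`: one row per protein, one
"observation" per reporter-channel ratio (e.g. ``116:114`` = ethanol-fed wild-type
male over dextrose-fed wild-type male). Each cell is an :class:`ObservationRatio`
holding the log2 of the reported protein ratio and, when available, the ratio-test
p-value produced by the quantification engine.

On disk a quant table is a delimited text file whose header names observation
columns ``"<num>:<den> log2R"`` and ``"<num>:<den> p"``; every other column is
either a core annotation (accession, protein_name, gene_symbol, function) or an
arbitrary extra annotation carried along verbatim. Missing cells are written as
``"-"`` and read back as missing (``-``, empty, ``NA`` and ``NaN`` all count).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import ContractError, FormatError, ValidationError

__all__ = [
    "ObservationRatio",
    "ProteinRecord",
    "QuantTable",
    "RegulatorEdge",
    "RegulatorNetwork",
    "read_quant_table",
    "write_quant_table",
    "re_reference",
    "read_network",
    "write_network",
]

#: Cell contents interpreted as "missing" on read.
MISSING_MARKERS = {"-", "", "na", "nan", "n/a"}

#: Core (non-observation) columns recognised by name.
CORE_COLUMNS = ("accession", "protein_name", "gene_symbol", "function")

_OBS_COLUMN = re.compile(r"^(?P<num>[^:\s]+):(?P<den>[^:\s]+)\s+(?P<kind>log2R|p)$")
_OBS_KEY = re.compile(r"^(?P<num>[^:\s]+):(?P<den>[^:\s]+)$")


def split_observation_key(key: str) -> tuple[str, str]:
    """Split a ``"num:den"`` observation key, validating its shape."""
    m = _OBS_KEY.match(key)
    if m is None:
        raise ValidationError(f"malformed observation key {key!r}; expected 'num:den'")
    return m.group("num"), m.group("den")


@dataclass
class ObservationRatio:
    """One protein's log2 expression ratio for one (numerator, denominator) channel pair."""

    numerator_channel: str
    denominator_channel: str
    log2_ratio: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.numerator_channel == self.denominator_channel:
            raise ValidationError(
                f"numerator and denominator channel are both {self.numerator_channel!r}"
            )
        if self.log2_ratio is not None and not math.isfinite(self.log2_ratio):
            raise ValidationError("log2_ratio must be finite when present")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.numerator_channel}:{self.denominator_channel}"

    @property
    def missing(self) -> bool:
        """True when no ratio was recorded for this channel pair."""
        return self.log2_ratio is None


@dataclass
class ProteinRecord:
    """A protein row: identifiers, free-text annotations and per-observation ratios."""

    accession: str
    gene_symbol: str = ""
    function_tag: str = ""
    protein_name: str = ""
    ratios: dict[str, ObservationRatio] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        for key in self.ratios:
            split_observation_key(key)

    def ratio(self, obs: str) -> ObservationRatio | None:
        return self.ratios.get(obs)

    def log2_ratio(self, obs: str) -> float | None:
        r = self.ratios.get(obs)
        return None if r is None else r.log2_ratio

    def p_value(self, obs: str) -> float | None:
        r = self.ratios.get(obs)
        return None if r is None else r.p_value


class QuantTable:
    """Ordered collection of :class:`ProteinRecord` over a fixed observation list."""

    def __init__(self, proteins: Iterable[ProteinRecord], observations: Iterable[str]):
        self.proteins: list[ProteinRecord] = list(proteins)
        self.observations: list[str] = list(observations)
        if len(set(self.observations)) != len(self.observations):
            raise ValidationError("duplicate observation keys")
        for key in self.observations:
            split_observation_key(key)
        seen: set[str] = set()
        for rec in self.proteins:
            if rec.accession in seen:
                raise ValidationError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
            extra = set(rec.ratios) - set(self.observations)
            if extra:
                raise ValidationError(
                    f"protein {rec.accession}: observation keys {sorted(extra)} "
                    "not declared in table"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.proteins)

    def __contains__(self, accession: str) -> bool:
        return any(rec.accession == accession for rec in self.proteins)

    def get(self, accession: str) -> ProteinRecord:
        for rec in self.proteins:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.proteins]

    def subset(self, accessions: Iterable[str]) -> "QuantTable":
        """Row subset in original order; unknown accessions raise ValidationError."""
        wanted = set(accessions)
        unknown = wanted - set(self.accessions)
        if unknown:
            raise ValidationError(f"accessions not in table: {sorted(unknown)}")
        return QuantTable(
            [rec for rec in self.proteins if rec.accession in wanted],
            self.observations,
        )

    def to_frame(self, value: str = "log2_ratio"):
        """Protein x observation matrix of ``log2_ratio`` or ``p_value`` as a DataFrame.

        Missing cells become NaN. Index is accession, columns are observation keys.
        """
        import pandas as pd

        if value not in ("log2_ratio", "p_value"):
            raise ContractError(f"value must be 'log2_ratio' or 'p_value', got {value!r}")
        data = {
            obs: [
                getattr(rec.ratios[obs], value)
                if obs in rec.ratios and getattr(rec.ratios[obs], value) is not None
                else math.nan
                for rec in self.proteins
            ]
            for obs in self.observations
        }
        return pd.DataFrame(data, index=self.accessions, columns=self.observations)

    def gene_symbols(self) -> dict[str, str]:
        return {rec.accession: rec.gene_symbol for rec in self.proteins}


def _parse_cell(text: str) -> float | None:
    if text.strip().lower() in MISSING_MARKERS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"cannot parse numeric cell {text!r}") from exc


def read_quant_table(path: str | Path, delimiter: str = "\t") -> QuantTable:
    """Read a quant table from a delimited text file.

    The header must contain an ``accession`` column; observation columns are
    recognised by the ``"num:den log2R"`` / ``"num:den p"`` convention. Any header
    cell containing a ``:`` that does not match that convention is rejected as a
    format error naming the offending column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header row") from None
        obs_columns: dict[int, tuple[str, str]] = {}  # col index -> (obs key, kind)
        other_columns: dict[int, str] = {}
        observations: list[str] = []
        for i, name in enumerate(header):
            name = name.strip()
            m = _OBS_COLUMN.match(name)
            if m:
                key = f"{m.group('num')}:{m.group('den')}"
                obs_columns[i] = (key, m.group("kind"))
                if key not in observations:
                    observations.append(key)
            elif ":" in name:
                raise FormatError(
                    f"{path}: malformed observation column {name!r}; "
                    "expected '<num>:<den> log2R' or '<num>:<den> p'"
                )
            else:
                other_columns[i] = name
        if "accession" not in other_columns.values():
            raise FormatError(f"{path}: header has no 'accession' column")

        proteins: list[ProteinRecord] = []
        for row in reader:
            if not row or all(not cell.strip() for cell in row):
                continue
            core = {name: "" for name in CORE_COLUMNS}
            annotations: dict[str, str] = {}
            values: dict[str, dict[str, float | None]] = {}
            for i, cell in enumerate(row):
                if i in obs_columns:
                    key, kind = obs_columns[i]
                    values.setdefault(key, {})[kind] = _parse_cell(cell)
                elif i in other_columns:
                    name = other_columns[i]
                    if name in core:
                        core[name] = cell.strip()
                    else:
                        annotations[name] = cell.strip()
            ratios = {}
            for key, kv in values.items():
                num, den = split_observation_key(key)
                log2r = kv.get("log2R")
                p = kv.get("p")
                if log2r is None:
                    p = None  # a dash row: no ratio means no ratio test either
                ratios[key] = ObservationRatio(num, den, log2r, p)
            proteins.append(
                ProteinRecord(
                    accession=core["accession"],
                    gene_symbol=core["gene_symbol"],
                    function_tag=core["function"],
                    protein_name=core["protein_name"],
                    ratios=ratios,
                    annotations=annotations,
                )
            )
    return QuantTable(proteins, observations)


def write_quant_table(table: QuantTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a quant table; missing cells are encoded as ``-``.

    Columns: the four core annotations, any extra annotations (union over rows,
    first-seen order), then per observation a ``log2R`` and a ``p`` column.
    """
    path = Path(path)
    extra: list[str] = []
    for rec in table.proteins:
        for name in rec.annotations:
            if name not in extra:
                extra.append(name)
    header = list(CORE_COLUMNS) + extra
    for obs in table.observations:
        header += [f"{obs} log2R", f"{obs} p"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        for rec in table.proteins:
            row = [rec.accession, rec.protein_name, rec.gene_symbol, rec.function_tag]
            row += [rec.annotations.get(name, "") for name in extra]
            for obs in table.observations:
                r = rec.ratios.get(obs)
                if r is None or r.log2_ratio is None:
                    row += ["-", "-"]
                else:
                    row.append(repr(r.log2_ratio))
                    row.append("-" if r.p_value is None else repr(r.p_value))
            writer.writerow(row)


def re_reference(table: QuantTable, obs_a: str, obs_b: str) -> QuantTable:
    """Derive the observation ``num_a:num_b`` from two same-denominator observations.

    log2(a/b) = log2(a/d) - log2(b/d); the derived p-value is left missing because
    it is not computable from ratio-level summaries. Returns a new table with the
    derived observation appended (or the original if it already exists).
    """
    for obs in (obs_a, obs_b):
        if obs not in table.observations:
            raise ContractError(f"observation {obs!r} not in table")
    num_a, den_a = split_observation_key(obs_a)
    num_b, den_b = split_observation_key(obs_b)
    if den_a != den_b:
        raise ContractError(
            f"cannot re-reference {obs_a!r} against {obs_b!r}: denominators differ"
        )
    derived_key = f"{num_a}:{num_b}"
    if derived_key in table.observations:
        return table
    proteins = []
    for rec in table.proteins:
        ratios = dict(rec.ratios)
        la, lb = rec.log2_ratio(obs_a), rec.log2_ratio(obs_b)
        value = None if la is None or lb is None else la - lb
        ratios[derived_key] = ObservationRatio(num_a, num_b, value, None)
        proteins.append(
            ProteinRecord(
                accession=rec.accession,
                gene_symbol=rec.gene_symbol,
                function_tag=rec.function_tag,
                protein_name=rec.protein_name,
                ratios=ratios,
                annotations=dict(rec.annotations),
            )
        )
    return QuantTable(proteins, table.observations + [derived_key])


# ---------------------------------------------------------------------------
# Regulator networks


_SIGN_TOKENS: Mapping[str, int | None] = {
    "+1": 1,
    "+": 1,
    "1": 1,
    "-1": -1,
    "-": -1,
    "?": None,
    "0": None,
    "na": None,
}


@dataclass(frozen=True)
class RegulatorEdge:
    """A signed regulator -> target relation.

    ``sign`` is +1 when the active regulator up-regulates the target, -1 when it
    down-regulates it, and None when the direction of regulation is not known
    (such edges contribute to overlap counting but not to consistency counting).
    """

    regulator: str
    target: str
    sign: int | None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1, None):
            raise ValidationError(f"edge sign must be +1, -1 or None, got {self.sign!r}")


class RegulatorNetwork:
    """An edge list of signed regulator -> target relations."""

    def __init__(self, edges: Iterable[RegulatorEdge]):
        self.edges: list[RegulatorEdge] = list(edges)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            pair = (e.regulator, e.target)
            if pair in seen:
                raise ValidationError(f"duplicate edge {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> list[str]:
        out: list[str] = []
        for e in self.edges:
            if e.regulator not in out:
                out.append(e.regulator)
        return out

    def targets_of(self, regulator: str) -> list[RegulatorEdge]:
        return [e for e in self.edges if e.regulator == regulator]


def read_network(path: str | Path, delimiter: str = "\t") -> RegulatorNetwork:
    """Read a 3-column regulator/target/sign TSV into a :class:`RegulatorNetwork`."""
    path = Path(path)
    edges: list[RegulatorEdge] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if lineno == 1 and row[0].strip().lower() == "regulator":
                continue  # optional header
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            regulator, target, sign_text = (cell.strip() for cell in row[:3])
            token = sign_text.lower()
            if token not in _SIGN_TOKENS:
                raise FormatError(
                    f"{path}:{lineno}: sign {sign_text!r} not one of +1/-1/+/-/?/0/NA"
                )
            edges.append(RegulatorEdge(regulator, target, _SIGN_TOKENS[token]))
    return RegulatorNetwork(edges)


def write_network(network: RegulatorNetwork, path: str | Path, delimiter: str = "\t") -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["regulator", "target", "sign"])
        for e in network.edges:
            sign = "?" if e.sign is None else f"{e.sign:+d}"
            writer.writerow([e.regulator, e.target, sign])
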