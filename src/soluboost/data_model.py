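"""Core record and descriptor types for organic-solvent solubility data.

A solubility *corpus* is a flat table of equilibrium measurements — one row
per (solute, solvent, temperature) with the mole-fraction solubility x — plus
two small descriptor tables:

* per-solute melting properties: melting temperature Tm, enthalpy of fusion
  ΔHfus at Tm, the two coefficients (q, r) of the linear heat-capacity
  difference ΔCp(T) = q + r·(T − Tm) between supercooled liquid and solid,
  and the total Hansen solubility parameter;
* per-solvent bulk properties: static dielectric constant and normal boiling
  point, cheap proxies for solvent polarity and cohesive interactions.

The packaged fixtures cover five pharmaceutical model solutes (butyl paraben,
fenoxycarb, fenofibrate, risperidone, butamben) and nine common organic
solvents.  Butamben's row is provisional except for Tm: the printed source
table is typographically ambiguous for that compound, so the remaining fields
are plausible placeholders that a user descriptor file should override when
real values are available.

File formats are plain delimited text (UTF-8, '.' decimal point, '#' comment
lines allowed):

* records:  header ``solute,solvent,T_K,x``
* solutes:  header ``name,Tm_K,dHfus_kJ_mol,q_J_K_mol,r_J_K2_mol,hansen_MPa05``
* solvents: header ``name,dielectric,bp_K``
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SolubilityRecord",
    "SoluteDescriptors",
    "SolventDescriptors",
    "Corpus",
    "CorpusReport",
    "SchemaError",
    "RecordParseError",
    "RecordValidationError",
    "DuplicateRecordError",
    "DescriptorLookupError",
    "normalize_name",
    "read_records",
    "write_records",
    "load_descriptors",
    "packaged_solutes",
    "packaged_solvents",
    "assemble_corpus",
    "validate_corpus",
]

RECORD_COLUMNS = ("solute", "solvent", "T_K", "x")
SOLUTE_COLUMNS = ("name", "Tm_K", "dHfus_kJ_mol", "q_J_K_mol", "r_J_K2_mol", "hansen_MPa05")
SOLVENT_COLUMNS = ("name", "dielectric", "bp_K")


class SchemaError(ValueError):
    """A delimited file is missing a required column."""


class RecordParseError(ValueError):
    """A data row could not be parsed (carries the 1-based line number)."""


class RecordValidationError(ValueError):
    """A parsed value violates a physical invariant (e.g. x outside (0, 1])."""


class DuplicateRecordError(ValueError):
    """The same (solute, solvent, T) triple appears more than once."""


class DescriptorLookupError(KeyError):
    """A compound named in the records has no descriptor entry."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0] if self.args else ""


def normalize_name(name: str) -> str:
    """Lower-case and collapse internal/surrounding whitespace."""
    return " ".join(str(name).split()).lower()


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium solubility observation."""

    solute: str
    solvent: str
    temperature: float  # K
    x: float  # mole fraction, in (0, 1]

    def __post_init__(self) -> None:
        if not str(self.solute).strip():
            raise RecordValidationError("solute name must be non-empty")
        if not str(self.solvent).strip():
            raise RecordValidationError("solvent name must be non-empty")
        if not self.temperature > 0:
            raise RecordValidationError(f"temperature must be positive, got {self.temperature}")
        if not (0 < self.x <= 1):
            raise RecordValidationError(f"mole fraction must lie in (0, 1], got {self.x}")

    @property
    def key(self) -> tuple[str, str, float]:
        return (normalize_name(self.solute), normalize_name(self.solvent), self.temperature)


@dataclass(frozen=True)
class SoluteDescriptors:
    """Thermodynamic descriptors of a solute.

    dHfus is stored in kJ/mol exactly as tabulated; thermodynamic formulas
    convert to J/mol internally.
    """

    name: str
    Tm: float  # K
    dHfus: float  # kJ/mol at Tm
    q: float  # J/(K mol), ΔCp at Tm
    r: float  # J/(K² mol), slope of ΔCp in T
    hansen: float  # MPa^0.5

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise RecordValidationError(f"{self.name}: Tm must be positive")
        if not self.dHfus > 0:
            raise RecordValidationError(f"{self.name}: dHfus must be positive")
        if not self.q > 0:
            raise RecordValidationError(f"{self.name}: q must be positive")


@dataclass(frozen=True)
class SolventDescriptors:
    """Bulk descriptors of a solvent."""

    name: str
    dielectric: float  # dimensionless static dielectric constant
    bp: float  # K, normal boiling point

    def __post_init__(self) -> None:
        if not self.dielectric > 1:
            raise RecordValidationError(f"{self.name}: dielectric constant must exceed 1")
        if not self.bp > 0:
            raise RecordValidationError(f"{self.name}: boiling point must be positive")


@dataclass
class Corpus:
    """Solubility records together with the descriptor tables they reference.

    Invariants (checked on construction): every record's solute and solvent
    resolve to a descriptor entry, and no (solute, solvent, T) triple repeats.
    """

    records: list[SolubilityRecord]
    solutes: dict[str, SoluteDescriptors] = field(default_factory=dict)
    solvents: dict[str, SolventDescriptors] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.solutes = {normalize_name(k): v for k, v in self.solutes.items()}
        self.solvents = {normalize_name(k): v for k, v in self.solvents.items()}
        _check_duplicates(self.records)
        for rec in self.records:
            if normalize_name(rec.solute) not in self.solutes:
                raise DescriptorLookupError(f"no solute descriptors for {rec.solute!r}")
            if normalize_name(rec.solvent) not in self.solvents:
                raise DescriptorLookupError(f"no solvent descriptors for {rec.solvent!r}")

    def __len__(self) -> int:
        return len(self.records)

    def solute_of(self, record: SolubilityRecord) -> SoluteDescriptors:
        return self.solutes[normalize_name(record.solute)]

    def solvent_of(self, record: SolubilityRecord) -> SolventDescriptors:
        return self.solvents[normalize_name(record.solvent)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "solute": [r.solute for r in self.records],
                "solvent": [r.solvent for r in self.records],
                "T_K": [r.temperature for r in self.records],
                "x": [r.x for r in self.records],
            }
        )

    def subset(self, keys: Iterable[tuple[str, str, float]]) -> "Corpus":
        """Records whose normalized (solute, solvent, T) key is in ``keys``."""
        wanted = set(keys)
        recs = [r for r in self.records if r.key in wanted]
        return Corpus(recs, dict(self.solutes), dict(self.solvents))


def _check_duplicates(records: Iterable[SolubilityRecord]) -> None:
    seen: set[tuple[str, str, float]] = set()
    for rec in records:
        if rec.key in seen:
            raise DuplicateRecordError(
                f"duplicate record for (solute={rec.solute!r}, solvent={rec.solvent!r}, "
                f"T={rec.temperature} K)"
            )
        seen.add(rec.key)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _read_table(path_or_buf, required: tuple[str, ...], delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep=delimiter, comment="#", skip_blank_lines=True, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_records(path, delimiter: str = ",") -> list[SolubilityRecord]:
    """Parse a records file into :class:`SolubilityRecord`\\ s, in file order.

    Raises :class:`SchemaError` for a missing column, :class:`RecordParseError`
    (with the offending line number) for non-numeric T or x,
    :class:`RecordValidationError` for out-of-range values and
    :class:`DuplicateRecordError` for repeated (solute, solvent, T) triples.
    """
    df = _read_table(path, RECORD_COLUMNS, delimiter)
    records: list[SolubilityRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header
        try:
            temperature = float(getattr(row, "T_K"))
            x = float(row.x)
        except (TypeError, ValueError) as exc:
            raise RecordParseError(f"line {line_no}: non-numeric T_K or x ({exc})") from None
        records.append(SolubilityRecord(str(row.solute), str(row.solvent), temperature, x))
    _check_duplicates(records)
    return records


def write_records(records: Iterable[SolubilityRecord], path, delimiter: str = ",",
                  header_comments: Iterable[str] = ()) -> None:
    """Write records as delimited text; inverse of :func:`read_records`.

    Floats are written with ``repr``, the shortest exact decimal form, so a
    read→write→read cycle is the identity field-for-field.
    """
    lines = [f"# {c}" for c in header_comments]
    lines.append(delimiter.join(RECORD_COLUMNS))
    for rec in records:
        lines.append(delimiter.join((rec.solute, rec.solvent, repr(float(rec.temperature)),
                                     repr(float(rec.x)))))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _solutes_from_frame(df: pd.DataFrame) -> dict[str, SoluteDescriptors]:
    out: dict[str, SoluteDescriptors] = {}
    for row in df.itertuples(index=False):
        d = SoluteDescriptors(
            name=str(row.name).strip(),
            Tm=float(row.Tm_K),
            dHfus=float(row.dHfus_kJ_mol),
            q=float(row.q_J_K_mol),
            r=float(row.r_J_K2_mol),
            hansen=float(row.hansen_MPa05),
        )
        out[normalize_name(d.name)] = d
    return out


def _solvents_from_frame(df: pd.DataFrame) -> dict[str, SolventDescriptors]:
    out: dict[str, SolventDescriptors] = {}
    for row in df.itertuples(index=False):
        d = SolventDescriptors(name=str(row.name).strip(), dielectric=float(row.dielectric),
                               bp=float(row.bp_K))
        out[normalize_name(d.name)] = d
    return out


def load_descriptors(solute_path=None, solvent_path=None, delimiter: str = ","):
    """Load solute and solvent descriptor tables, keyed by normalized name.

    ``None`` for either path falls back to the packaged fixture table.
    """
    if solute_path is None:
        solutes = packaged_solutes()
    else:
        solutes = _solutes_from_frame(_read_table(solute_path, SOLUTE_COLUMNS, delimiter))
    if solvent_path is None:
        solvents = packaged_solvents()
    else:
        solvents = _solvents_from_frame(_read_table(solvent_path, SOLVENT_COLUMNS, delimiter))
    return solutes, solvents


def _packaged_csv(name: str) -> io.StringIO:
    text = resources.files("soluboost").joinpath("data", name).read_text(encoding="utf-8")
    return io.StringIO(text)


def packaged_solutes() -> dict[str, SoluteDescriptors]:
    """The packaged five-solute descriptor table (butamben row provisional)."""
    return _solutes_from_frame(_read_table(_packaged_csv("solutes.csv"), SOLUTE_COLUMNS))


def packaged_solvents() -> dict[str, SolventDescriptors]:
    """The packaged nine-solvent descriptor table."""
    return _solvents_from_frame(_read_table(_packaged_csv("solvents.csv"), SOLVENT_COLUMNS))


def assemble_corpus(records_path, solute_path=None, solvent_path=None,
                    delimiter: str = ",") -> Corpus:
    """Read records and descriptors and assemble a validated :class:`Corpus`."""
    records = read_records(records_path, delimiter)
    solutes, solvents = load_descriptors(solute_path, solvent_path, delimiter)
    return Corpus(records, solutes, solvents)


# ---------------------------------------------------------------------------
# validation report


@dataclass
class CorpusReport:
    """Report-only summary of a corpus: group sizes, T-ranges, breaches."""

    groups: pd.DataFrame  # columns: solute, solvent, n, T_min, T_max
    breaches: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def ok(self) -> bool:
        return not self.breaches


def validate_corpus(records: "Corpus | Iterable[SolubilityRecord]",
                    solutes: Mapping[str, SoluteDescriptors] | None = None,
                    solvents: Mapping[str, SolventDescriptors] | None = None) -> CorpusReport:
    """Summarise per-(solute, solvent) counts and flag invariant breaches.

    Accepts a :class:`Corpus` (descriptor maps taken from it) or a bare
    record iterable plus optional maps.  Never mutates or rejects the data —
    breaches are listed in the report.
    """
    if isinstance(records, Corpus):
        solutes = solutes if solutes is not None else records.solutes
        solvents = solvents if solvents is not None else records.solvents
        records = records.records
    records = list(records)
    breaches: list[str] = []
    seen: set[tuple[str, str, float]] = set()
    for rec in records:
        if rec.key in seen:
            breaches.append(f"duplicate triple {rec.key}")
        seen.add(rec.key)
        if solutes is not None and normalize_name(rec.solute) not in solutes:
            breaches.append(f"unknown solute {rec.solute!r}")
        if solvents is not None and normalize_name(rec.solvent) not in solvents:
            breaches.append(f"unknown solvent {rec.solvent!r}")

    if records:
        df = pd.DataFrame(
            {
                "solute": [normalize_name(r.solute) for r in records],
                "solvent": [normalize_name(r.solvent) for r in records],
                "T_K": [r.temperature for r in records],
            }
        )
        groups = (
            df.groupby(["solute", "solvent"], sort=True)["T_K"]
            .agg(n="size", T_min="min", T_max="max")
            .reset_index()
        )
    else:
        groups = pd.DataFrame(columns=["solute", "solvent", "n", "T_min", "T_max"])
    return CorpusReport(groups=groups, breaches=breaches)
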