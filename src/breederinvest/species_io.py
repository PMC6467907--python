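"""Read, validate, and write species-trait tables and model configuration.

Trait tables are delimited text (comma by default, tab via the ``delimiter``
argument) with a header row and columns::

    species, taxon_group, n_offspring, offspring_mass, breeder_mass
    [, brood_masses][, source]

``brood_masses`` holds semicolon-separated per-offspring masses.  Trait cells
may contain a plain number, a printed range ``a-b`` (averaged to the
midpoint), or several source values separated by ``|`` (averaged), reflecting
how life-history compilations report heterogeneous measurements.  Rows that
fail validation are skipped and itemised in an issue report rather than
aborting the run: multi-source trait data is dirty as a rule.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .model_core import (
    ClassificationResult,
    ConfigError,
    InvalidInputError,
    ModelParams,
    SpeciesRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "TableSchemaError",
    "RowIssue",
    "parse_quantity",
    "read_species_table",
    "write_species_table",
    "write_results",
    "load_params",
    "example_species_path",
]

REQUIRED_COLUMNS = ("species", "taxon_group", "n_offspring", "offspring_mass", "breeder_mass")
OPTIONAL_COLUMNS = ("brood_masses", "source")
RESULT_COLUMNS = ("S", "P", "C", "G", "category", "effective_n", "singleton_rule_applied")

_PARAM_KEYS = ("w", "s_setpoint", "n_setpoint", "n_substitute")


class ParseError(ValueError):
    """A trait cell could not be interpreted as a number, range, or list."""


class TableSchemaError(ValueError):
    """The input table is missing required columns or is unreadable."""


@dataclass(frozen=True)
class RowIssue:
    """One skipped input row: its 1-based data-row number and the reason."""

    row: int
    species: str
    reason: str

    def __str__(self) -> str:
        return f"row {self.row} ({self.species or '?'}): {self.reason}"


# A number with optional thousands separators, decimals, and exponent.
_NUM = r"(?:\d{1,3}(?:,\d{3})+|\d+)(?:\.\d+)?(?:[eE][+-]?\d+)?"
_RANGE_RE = re.compile(rf"^\s*({_NUM})\s*[-–−]\s*({_NUM})\s*$")
_SINGLE_RE = re.compile(rf"^\s*({_NUM})\s*$")


def _parse_scalar(token: str) -> float:
    m = _RANGE_RE.match(token)
    if m:
        lo = float(m.group(1).replace(",", ""))
        hi = float(m.group(2).replace(",", ""))
        if lo > hi:
            raise ParseError(f"range {token!r} has lower bound above upper bound")
        return (lo + hi) / 2.0
    m = _SINGLE_RE.match(token)
    if m:
        return float(m.group(1).replace(",", ""))
    # fall back to the plain float grammar so "-3" surfaces as a sign error,
    # not an unparseable cell
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"cannot parse quantity {token!r}") from None
    if value < 0:
        raise ParseError(f"negative quantity {token!r} is not a valid trait value")
    return value


def parse_quantity(cell: Union[str, float, int]) -> float:
    """Parse one trait cell to a number.

    Plain numbers pass through; ``"a-b"`` ranges (hyphen, en-dash, or minus
    sign) return the midpoint; ``"x|y|z"`` multi-source lists return the
    arithmetic mean; thousands separators are accepted.

    >>> parse_quantity("2-6")
    4.0
    >>> parse_quantity("100|200|300")
    200.0
    """
    if isinstance(cell, (int, float)):
        if cell < 0:
            raise ParseError(f"negative quantity {cell!r} is not a valid trait value")
        return float(cell)
    text = cell.strip()
    if not text:
        raise ParseError("empty cell")
    values = [_parse_scalar(tok) for tok in text.split("|")]
    return sum(values) / len(values)


def _parse_brood(cell: str) -> Optional[tuple[float, ...]]:
    text = cell.strip()
    if not text:
        return None
    masses = []
    for tok in text.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        value = float(tok)
        if value < 0:
            raise ParseError(f"negative brood mass {tok!r}")
        masses.append(value)
    if len(masses) < 2:
        raise ParseError("brood_masses needs at least 2 entries")
    return tuple(masses)


def read_species_table(
    path: Union[str, Path], delimiter: str = ","
) -> tuple[list[SpeciesRecord], list[RowIssue]]:
    """Read and validate a species-trait table.

    Returns ``(records, issues)``: rows failing parsing or validation are
    skipped and itemised in ``issues`` with their 1-based data-row number.
    A missing file or missing required column is fatal
    (:class:`TableSchemaError`).
    """
    path = Path(path)
    if not path.exists():
        raise TableSchemaError(f"species table not found: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed delimited text
        raise TableSchemaError(f"cannot read species table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required columns {missing}")

    records: list[SpeciesRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        name = rowd.get("species", "").strip()
        try:
            brood_cell = rowd.get("brood_masses", "")
            record = SpeciesRecord(
                name=name,
                taxon_group=rowd["taxon_group"].strip(),
                n_offspring=parse_quantity(rowd["n_offspring"]),
                offspring_mass=parse_quantity(rowd["offspring_mass"]),
                breeder_mass=parse_quantity(rowd["breeder_mass"]),
                brood_masses=_parse_brood(brood_cell),
                source=rowd.get("source", "").strip() or None,
            )
        except InvalidInputError as exc:
            issues.append(RowIssue(i, name, _strip_prefix(str(exc), name)))
            continue
        except (ParseError, ValueError) as exc:
            issues.append(RowIssue(i, name, str(exc)))
            continue
        records.append(record)

    logger.info(
        "read %d rows from %s: kept %d, skipped %d", len(df), path, len(records), len(issues)
    )
    for issue in issues:
        logger.warning("skipped %s", issue)
    return records, issues


def _strip_prefix(message: str, name: str) -> str:
    prefix = f"{name}: "
    return message[len(prefix):] if message.startswith(prefix) else message


def _format_brood(brood: Optional[Sequence[float]]) -> str:
    if brood is None:
        return ""
    return ";".join(repr(float(m)) for m in brood)


def write_species_table(
    records: Sequence[SpeciesRecord], path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write species records back out in the input-table schema."""
    rows = [
        {
            "species": r.name,
            "taxon_group": r.taxon_group,
            "n_offspring": repr(float(r.n_offspring)),
            "offspring_mass": repr(float(r.offspring_mass)),
            "breeder_mass": repr(float(r.breeder_mass)),
            "brood_masses": _format_brood(r.brood_masses),
            "source": r.source or "",
        }
        for r in records
    ]
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=delimiter, index=False)


def write_results(
    results: Sequence[ClassificationResult], path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write classification results as the input schema plus model columns.

    Adds ``S``, ``P``, ``C``, ``G`` (empty — not zero — when no brood masses
    were available), ``category``, ``effective_n`` and
    ``singleton_rule_applied``.  Numbers are rendered at full precision so the
    table round-trips through :func:`read_species_table` without loss.
    """
    rows = []
    for res in results:
        r = res.record
        rows.append(
            {
                "species": r.name,
                "taxon_group": r.taxon_group,
                "n_offspring": repr(float(r.n_offspring)),
                "offspring_mass": repr(float(r.offspring_mass)),
                "breeder_mass": repr(float(r.breeder_mass)),
                "brood_masses": _format_brood(r.brood_masses),
                "source": r.source or "",
                "S": repr(res.s_value),
                "P": repr(res.p_value),
                "C": "" if res.c_value is None else repr(res.c_value),
                "G": "" if res.g_value is None else repr(res.g_value),
                "category": res.category.value,
                "effective_n": repr(res.effective_n),
                "singleton_rule_applied": str(res.singleton_rule_applied),
            }
        )
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS) + list(RESULT_COLUMNS)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=delimiter, index=False)


def load_params(path: Union[str, Path]) -> ModelParams:
    """Load :class:`ModelParams` from a JSON or YAML config document.

    Recognised keys: ``w``, ``s_setpoint``, ``n_setpoint``, ``n_substitute``
    — all optional, model defaults otherwise.  Unknown keys are a
    :class:`ConfigError` (they are usually typos that would silently revert a
    parameter to its default).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(doc).__name__}")
    unknown = sorted(set(doc) - set(_PARAM_KEYS))
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}; expected {_PARAM_KEYS}")
    try:
        return ModelParams(**{k: float(v) for k, v in doc.items()})
    except (TypeError, ValueError) as exc:
        if isinstance(exc, InvalidInputError):
            raise
        raise ConfigError(f"{path}: non-numeric parameter value: {exc}") from exc


def example_species_path() -> Path:
    """Path to the packaged eight-species demonstration table.

    The rows span the four selection categories (fish and a sea turtle under
    predation selection, a songbird and an elephant under scarcity selection,
    two apex predators under weak selection, two social insects under
    convergent selection).  Trait values are illustrative order-of-magnitude
    figures for demonstration and testing, not a curated dataset.
    """
    return Path(str(resources.files("breederinvest").joinpath("data/example_species.csv")))
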