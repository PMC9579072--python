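"""Schema validation for survey CSV files.

The survey CSV dialect is UTF-8, comma-separated, '.' decimal, with a
mandatory header row and the fixed column order documented in
:data:`benthme.simulate.SURVEY_COLUMNS`.  Validation reports every
violation with the 1-based file line number (header = line 1).
"""

from __future__ import annotations

import pandas as pd

from .design import LINES, PERIODS, ZONES
from .simulate import SURVEY_COLUMNS, TAXA

__all__ = ["SurveyValidationError", "validate_survey_table", "validate_survey_csv"]

_ALLOWED_PERIODS = set(PERIODS) | {"H"}
_ALLOWED_DESIGNS = {"grid", "hotspot"}
_ALLOWED_SEDIMENTS = {"fine", "medium"}


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the schema; carries a line-
    numbered error report."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"survey table failed validation:\n{preview}{more}")


def validate_survey_table(table: pd.DataFrame, *, line_offset: int = 2) -> pd.DataFrame:
    """Validate an in-memory survey table; returns it unchanged if clean.

    ``line_offset`` maps row position to file line (2 = first data row of a
    CSV with a header).
    """
    errors: list[str] = []
    missing = [c for c in SURVEY_COLUMNS if c not in table.columns]
    if missing:
        raise SurveyValidationError([f"missing columns: {', '.join(missing)}"])

    def line(i: int) -> int:
        return i + line_offset

    for i, row in enumerate(table.itertuples(index=False)):
        if row.zone not in ZONES:
            errors.append(
                f"line {line(i)}: unknown zone {row.zone!r}; allowed {ZONES}"
            )
        if str(row.period) not in _ALLOWED_PERIODS:
            errors.append(
                f"line {line(i)}: unknown period {row.period!r}; "
                f"allowed {sorted(_ALLOWED_PERIODS)}"
            )
        if row.design not in _ALLOWED_DESIGNS:
            errors.append(f"line {line(i)}: unknown design {row.design!r}")
        if row.line not in LINES:
            errors.append(f"line {line(i)}: unknown line {row.line!r}")
        if row.sediment not in _ALLOWED_SEDIMENTS:
            errors.append(f"line {line(i)}: unknown sediment {row.sediment!r}")
        if row.taxon_group not in TAXA and row.taxon_group != "total_prey":
            errors.append(f"line {line(i)}: unknown taxon {row.taxon_group!r}")
        try:
            depth = float(row.depth_m)
            if not depth > 0:
                errors.append(f"line {line(i)}: depth_m must be > 0, got {depth}")
        except (TypeError, ValueError):
            errors.append(f"line {line(i)}: non-numeric depth_m {row.depth_m!r}")
        try:
            b = float(row.biomass_wet_g_per_m2)
            if b < 0:
                errors.append(f"line {line(i)}: negative biomass {b}")
        except (TypeError, ValueError):
            errors.append(
                f"line {line(i)}: non-numeric biomass {row.biomass_wet_g_per_m2!r}"
            )

    dup = table.duplicated(
        subset=["station_id", "period", "taxon_group", "replicate_index"], keep="first"
    )
    for i in table.index[dup.to_numpy()]:
        pos = table.index.get_loc(i)
        errors.append(
            f"line {line(pos)}: duplicate replicate_index within "
            "(station_id, period, taxon_group)"
        )

    if errors:
        raise SurveyValidationError(errors)
    return table


def validate_survey_csv(path: str) -> pd.DataFrame:
    """Read and schema-check a survey CSV; raises SurveyValidationError
    (line-numbered) on violations, pandas errors on malformed CSV."""
    table = pd.read_csv(path, dtype={"period": str, "replicate_index": "Int64"})
    return validate_survey_table(table)
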