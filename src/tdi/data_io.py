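"""Reading, validating and writing long-format agreement data and reports.

The universal input record is :class:`AgreementData`: long-format
measurements of one continuous variable taken by exactly two devices, with
``m`` replicates per subject x device cell, plus optional covariates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = [
    "AgreementData",
    "read_agreement_csv",
    "write_agreement_csv",
    "melt_wide",
    "write_report",
]

CANONICAL_COLUMNS = ("subject", "device", "replicate", "value")


@dataclass(frozen=True)
class AgreementData:
    """Validated long-format agreement data from two measurement devices.

    ``devices`` fixes the sign convention: the mean difference ``mu_D`` is
    the effect of ``devices[1]`` minus ``devices[0]``.  ``balanced`` is true
    iff every subject x device cell holds exactly ``m`` records (same ``m``
    everywhere); ``m`` is ``None`` for unbalanced data.
    """

    frame: pd.DataFrame = field(repr=False)
    devices: tuple[str, str]
    covariates: tuple[str, ...]
    n: int
    m: int | None
    balanced: bool

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        device_order: Sequence | None = None,
        covariates: Sequence[str] | None = None,
    ) -> "AgreementData":
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        frame = frame.copy()

        values = pd.to_numeric(frame["value"], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric or non-finite measurement value at row {row}: "
                f"{frame['value'].iloc[row]!r}"
            )
        frame["value"] = values.astype(float)

        labels = [str(d) for d in pd.unique(frame["device"])]
        if len(labels) != 2:
            raise DataError(f"expected exactly 2 device labels, found {labels}")
        frame["device"] = frame["device"].astype(str)
        if device_order is None:
            devices = tuple(sorted(labels))
        else:
            devices = tuple(str(d) for d in device_order)
            if len(devices) != 2 or set(devices) != set(labels):
                raise ConfigurationError(
                    f"device_order {devices} does not match labels {labels}"
                )

        try:
            frame["replicate"] = frame["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise DataError(f"replicate indices must be integers: {exc}") from None
        if (frame["replicate"] < 1).any():
            raise DataError("replicate indices must be 1-based positive integers")

        if covariates is None:
            covariates = tuple(c for c in frame.columns if c not in CANONICAL_COLUMNS)
        else:
            covariates = tuple(covariates)
            missing = [c for c in covariates if c not in frame.columns]
            if missing:
                raise ConfigurationError(f"covariate columns not found: {missing}")
        if covariates and frame[list(covariates)].isna().any().any():
            raise DataError("missing covariate values are not supported")

        if frame.duplicated(subset=["subject", "device", "replicate"]).any():
            raise DataError("duplicate (subject, device, replicate) records")
        counts = frame.groupby(["subject", "device"], sort=False).size()
        n = frame["subject"].nunique()
        if n < 1:
            raise DataError("no subjects found")
        full_grid = len(counts) == 2 * n
        balanced = full_grid and counts.nunique() == 1
        m = int(counts.iloc[0]) if balanced else None

        return cls(
            frame=frame.reset_index(drop=True),
            devices=devices,
            covariates=covariates,
            n=int(n),
            m=m,
            balanced=bool(balanced),
        )

    def balanced_values(self) -> np.ndarray:
        """Measurements as an ``(n, 2, m)`` array ordered by ``devices`` and
        replicate index.  Requires balanced data."""
        if not self.balanced:
            raise DataError("operation requires balanced data")
        frame = self.frame.sort_values(["subject", "device", "replicate"])
        wide = frame.pivot_table(
            index="subject", columns=["device", "replicate"], values="value",
            sort=True,
        )
        cols = [(d, r) for d in self.devices for r in sorted(set(frame["replicate"]))]
        return wide[cols].to_numpy().reshape(self.n, 2, self.m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgreementData):
            return NotImplemented
        meta = (self.devices, self.covariates, self.n, self.m, self.balanced) == (
            other.devices, other.covariates, other.n, other.m, other.balanced,
        )
        return meta and self.frame.equals(other.frame)


def read_agreement_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    device_order: Sequence | None = None,
) -> AgreementData:
    """Read long-format agreement data from a CSV file.

    ``column_map`` maps canonical names (``subject``, ``device``,
    ``replicate``, ``value``) to the file's column names.  Remaining columns
    are treated as covariates.  ``device_order`` fixes the sign of the mean
    difference (second minus first).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        unknown = [k for k in column_map if k not in CANONICAL_COLUMNS]
        if unknown:
            raise ConfigurationError(f"unknown canonical names in column_map: {unknown}")
        missing = [v for v in column_map.values() if v not in frame.columns]
        if missing:
            raise ConfigurationError(f"mapped columns absent from file: {missing}")
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    return AgreementData.from_frame(frame, device_order=device_order)


def write_agreement_csv(data: AgreementData, path) -> None:
    """Write ``data`` back to CSV in canonical column order (round-trips
    through :func:`read_agreement_csv`)."""
    cols = list(CANONICAL_COLUMNS) + list(data.covariates)
    # %.17g guarantees binary round-trip of float64 values
    data.frame[cols].to_csv(path, index=False, float_format="%.17g")


def melt_wide(
    frame: pd.DataFrame,
    subject: str,
    device_columns: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Melt a wide table (one column per device x replicate) into the long
    canonical layout.

    ``device_columns`` maps each device label to its ordered replicate
    columns, e.g. ``{"manual": ["man1", "man2"], "auto": ["auto1", "auto2"]}``.
    """
    rows = []
    for device, cols in device_columns.items():
        for rep, col in enumerate(cols, start=1):
            if col not in frame.columns:
                raise ConfigurationError(f"column {col!r} not in frame")
            part = pd.DataFrame(
                {
                    "subject": frame[subject],
                    "device": device,
                    "replicate": rep,
                    "value": frame[col],
                }
            )
            rows.append(part)
    return pd.concat(rows, ignore_index=True)


_FIELD_RENAMES = {"kappa_hat": "estimate", "p_kappa_hat": "estimate"}


def _record(result) -> dict:
    if isinstance(result, dict):
        rec = dict(result)
    elif dataclasses.is_dataclass(result):
        rec = dataclasses.asdict(result)
        rec["type"] = type(result).__name__
    else:
        raise ConfigurationError(f"cannot serialize result of type {type(result)!r}")
    for old, new in _FIELD_RENAMES.items():
        if old in rec:
            rec[new] = rec.pop(old)
    return rec


def write_report(results, path, format: str = "json") -> None:
    """Write analysis results (TDI/CP/comparator records or a simulation
    summary table) to ``path`` as JSON or CSV, at full float precision."""
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise DataError("refusing to write an empty report")
        if format == "json":
            path.write_text(results.to_json(orient="records", double_precision=15))
        elif format == "csv":
            results.to_csv(path, index=False)
        else:
            raise ConfigurationError(f"unknown report format {format!r}")
        return

    if not isinstance(results, Iterable) or isinstance(results, (str, bytes)):
        results = [results]
    records = [_record(r) for r in results]
    if not records:
        raise DataError("refusing to write an empty report")
    if format == "json":
        path.write_text(json.dumps(records, indent=2, default=str))
    elif format == "csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown report format {format!r}")
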