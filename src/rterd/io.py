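"""Reading and writing unit-interval samples; bundled application data.

Samples are plain text, one numeric value per line, or a single-column
CSV/TSV with an optional header line.  The bundled dataset is the failure
time of 50 components (in thousands of hours), a complete, right-skewed
reliability dataset on the unit interval.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .distribution import DataError, SampleData

__all__ = ["read_sample", "write_sample", "load_failure_times", "FAILURE_TIMES_FILE"]

FAILURE_TIMES_FILE = "failure_times.txt"


def _parse_line(token: str) -> float | None:
    token = token.strip().strip(",;\t ")
    if not token:
        return None
    return float(token)


def read_sample(path) -> SampleData:
    """Read a validated sample from a text file.

    One value per line (or single-column CSV/TSV); a single non-numeric
    header line is tolerated.  Parse and range errors name the offending
    line number.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    values: list[float] = []
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        # single-column CSV/TSV: take the sole field
        field = stripped.split(",")[0].split("\t")[0].strip()
        try:
            val = _parse_line(field)
        except ValueError:
            if lineno == 1 and not values:
                continue  # header line
            raise DataError(f"{path}:{lineno}: non-numeric value {field!r}") from None
        if val is None:
            continue
        if not np.isfinite(val) or val <= 0.0 or val > 1.0:
            raise DataError(f"{path}:{lineno}: value {val!r} outside (0, 1]")
        values.append(val)
    if not values:
        raise DataError(f"{path}: no observations found")
    return SampleData(values=np.asarray(values))


def write_sample(sample: SampleData, path) -> None:
    """Write one observation per line at full (round-trip) precision."""
    path = Path(path)
    with path.open("w") as fh:
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")


def load_failure_times() -> SampleData:
    """The bundled 50 component failure times (10^3 hours)."""
    ref = resources.files("rterd").joinpath("data", FAILURE_TIMES_FILE)
    with resources.as_file(ref) as p:
        return read_sample(p)
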