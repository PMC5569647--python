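"""Delimited-text readers and writers.

All files are plain CSV or TSV (delimiter auto-detected).  Time columns
hold decimal years; ISO dates (``1963-05-21``) are accepted and converted
on a 365.25-day year, with the conversion logged.

Formats
-------
* **event history** — lifelines with columns ``id, birth, death`` (an
  empty death cell marks right censoring), plus optional long-format
  observation rows ``id, time, value`` in a second file.
* **event matrix** — one row per individual, one labelled column per
  event (the general n-event layout); empty cells are unobserved events.
* **lifetable** — HMD-style columns ``Age, lx, dx, Lx, ex`` (``Age`` may
  end in ``+`` for the open age group); the radix is read from ``lx[0]``.
  Only ``Age`` and one of ``lx``/``dx`` are strictly required — the rest
  are rebuilt under the package's midpoint conventions if absent.
* **prevalence** — two columns: thanatological or chronological age, and
  prevalence in [0, 1].
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import iso_to_decimal_year
from .exceptions import FormatError
from .health import AgePrevalence, Lifetable, TTDPrevalence, build_lifetable
from .hexad import Lifeline, Observation

__all__ = [
    "read_event_history",
    "read_observations",
    "write_lifelines",
    "write_observations",
    "read_event_matrix",
    "read_lifetable",
    "write_lifetable",
    "read_ttd_prevalence",
    "read_age_prevalence",
]

log = logging.getLogger(__name__)

#: Significant digits used when writing numeric output (round-trip safe).
FLOAT_FORMAT = "%.17g"


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited file, sniffing comma vs tab; empty file -> empty frame."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        log.warning("%s is empty", path)
        return pd.DataFrame()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _to_years(raw: object, path: Path, column: str, row: int) -> float | None:
    """Parse a cell as decimal years, accepting ISO dates; None when empty."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        pass
    try:
        value = iso_to_decimal_year(s)
    except ValueError as exc:
        raise FormatError(
            f"{path}:{row}: cannot parse {column}={s!r} as decimal year or ISO date"
        ) from exc
    log.info("%s:%d: converted %s=%r to decimal year %.6f", path, row, column, s, value)
    return value


def read_event_history(
    path: str | Path,
    observations: str | Path | None = None,
    errors: str = "warn",
) -> tuple[list[Lifeline], list[Observation]]:
    """Read lifelines (and optionally observations) from delimited text.

    Malformed rows (missing id/birth, death < birth) are reported with
    their line numbers and either dropped (``errors="warn"``, default) or
    raised as one :class:`FormatError` listing the offending ids
    (``errors="raise"``).
    """
    if errors not in ("warn", "raise"):
        raise FormatError("errors must be 'warn' or 'raise'")
    path = Path(path)
    df = _read_table(path)
    lifelines: list[Lifeline] = []
    bad: list[str] = []
    if not df.empty:
        missing = {"id", "birth"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        has_death = "death" in df.columns
        for idx, row in df.iterrows():
            line = idx + 2  # header is line 1
            ident = row["id"]
            birth = _to_years(row["birth"], path, "birth", line)
            death = _to_years(row["death"], path, "death", line) if has_death else None
            if ident is None or str(ident).strip() == "" or birth is None:
                bad.append(f"{path}:{line}: missing id or birth")
                continue
            if death is not None and death < birth:
                bad.append(
                    f"{path}:{line}: id {ident}: death {death:g} precedes birth {birth:g}"
                )
                continue
            lifelines.append(Lifeline(id=str(ident).strip(), birth=birth, death=death))
    if bad:
        if errors == "raise":
            raise FormatError("; ".join(bad))
        for msg in bad:
            log.warning("rejected row: %s", msg)

    obs: list[Observation] = []
    if observations is not None:
        obs = read_observations(observations, errors=errors)
    return lifelines, obs


def read_observations(path: str | Path, errors: str = "warn") -> list[Observation]:
    """Read long-format observation rows ``id, time, value`` ."""
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        return []
    missing = {"id", "time"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    has_value = "value" in df.columns
    has_weight = "weight" in df.columns
    out: list[Observation] = []
    bad: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        time = _to_years(row["time"], path, "time", line)
        if str(row["id"]).strip() == "" or time is None:
            bad.append(f"{path}:{line}: missing id or time")
            continue
        value = _to_years(row["value"], path, "value", line) if has_value else None
        weight = _to_years(row["weight"], path, "weight", line) if has_weight else None
        out.append(
            Observation(
                id=str(row["id"]).strip(),
                time=time,
                value=value,
                weight=1.0 if weight is None else weight,
            )
        )
    if bad:
        if errors == "raise":
            raise FormatError("; ".join(bad))
        for msg in bad:
            log.warning("rejected row: %s", msg)
    return out


def write_lifelines(lifelines: Sequence[Lifeline], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [l.id for l in lifelines],
            "birth": [l.birth for l in lifelines],
            "death": [l.death if l.death is not None else np.nan for l in lifelines],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_observations(observations: Sequence[Observation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [o.id for o in observations],
            "time": [o.time for o in observations],
            "value": [o.value if o.value is not None else np.nan for o in observations],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_event_matrix(path: str | Path) -> pd.DataFrame:
    """One row per individual, one column per labelled event.

    Returns a DataFrame with an ``id`` column (created if absent) and one
    float column per event; empty cells become NaN (unobserved event).
    """
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        return pd.DataFrame()
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    for col in df.columns:
        if col == "id":
            continue
        df[col] = [
            _to_years(v, path, col, i + 2) for i, v in enumerate(df[col])
        ]
        df[col] = df[col].astype(float)
    return df


def read_lifetable(path: str | Path) -> Lifetable:
    """Read an HMD-style lifetable (columns ``Age, lx, dx, Lx, ex``).

    Ages must be single years, ascending from the first age; the open
    age group ("110+") is closed out.  Missing columns are reconstructed
    from lx (or dx) under the package's midpoint conventions.
    """
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        raise FormatError(f"{path}: empty lifetable")
    cols = {c.strip(): c for c in df.columns}
    if "Age" not in cols:
        # tolerate lower-case 'age'
        for c in df.columns:
            if c.strip().lower() == "age":
                cols["Age"] = c
                break
    if "Age" not in cols or ("lx" not in cols and "dx" not in cols):
        raise FormatError(f"{path}: need columns Age and lx (or dx); found {list(df.columns)}")
    ages = np.array([int(str(a).rstrip("+")) for a in df[cols["Age"]]])
    if np.any(np.diff(ages) != 1):
        raise FormatError(f"{path}: ages must be consecutive single years")
    if "lx" in cols:
        l = df[cols["lx"]].astype(float).to_numpy()
        radix = float(l[0])
        if radix <= 0 or np.any(np.diff(l) > 0):
            raise FormatError(f"{path}: lx must be positive at the radix and non-increasing")
        l_next = np.append(l[1:], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(l > 0, (l - l_next) / np.where(l > 0, l, 1.0), 1.0)
        q = np.clip(q, 0.0, 1.0)
    else:
        d = df[cols["dx"]].astype(float).to_numpy()
        radix = float(d.sum())
        l = radix - np.concatenate([[0.0], np.cumsum(d[:-1])])
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(l > 0, d / np.where(l > 0, l, 1.0), 1.0)
        q = np.clip(q, 0.0, 1.0)
    lt = build_lifetable(qx=q, radix=radix)
    # honour provided person-years / expectancies when present
    if "Lx" in cols and "ex" in cols:
        L = df[cols["Lx"]].astype(float).to_numpy()
        e = df[cols["ex"]].astype(float).to_numpy()
        lt = Lifetable(x=np.arange(len(ages)), l=lt.l, d=lt.d, L=L, e=e)
    if int(ages[0]) != 0:
        # shift the grid so x matches the file's ages
        lt = Lifetable(x=ages, l=lt.l, d=lt.d, L=lt.L, e=lt.e)
    return lt


def write_lifetable(lt: Lifetable, path: str | Path) -> None:
    pd.DataFrame(
        {"Age": lt.x, "lx": lt.l, "dx": lt.d, "Lx": lt.L, "ex": lt.e}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _read_prevalence(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    df = _read_table(path)
    if df.empty or df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (age/time, prevalence)")
    t = df.iloc[:, 0].astype(float).to_numpy()
    v = df.iloc[:, 1].astype(float).to_numpy()
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(np.diff(t) != 1):
        raise FormatError(f"{path}: the age/time grid must be consecutive integers")
    return t, v


def read_ttd_prevalence(path: str | Path) -> TTDPrevalence:
    """Two-column file: completed thanatological age (from 0), prevalence."""
    t, v = _read_prevalence(path)
    if t[0] != 0:
        raise FormatError(f"{path}: time-to-death schedule must start at t = 0")
    return TTDPrevalence(v)


def read_age_prevalence(path: str | Path) -> AgePrevalence:
    """Two-column file: completed chronological age, prevalence."""
    t, v = _read_prevalence(path)
    return AgePrevalence(v, age0=int(t[0]))
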