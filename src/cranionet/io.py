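"""Tabular input/output for craniometric data.

Two CSV dialects are used, both bit-faithful to the conventions of the
source tables:

* **Specimen tables** — one row per individual, columns
  ``specimen_id, site, sex`` followed by Martin codes.  A parenthesised
  cell like ``(132)`` is an estimated (reconstructed) value; an empty
  cell is missing.
* **Sample tables** — one row per population sample, columns
  ``sample_id, group_tag`` followed by ``<code>_n, <code>_mean,
  <code>_sd`` triples per Martin code.  An empty ``sd`` cell means the
  SD is absent (n = 1).

A PHYLIP square distance-matrix writer/reader is also provided for
interoperability with phylogenetics tools (labels sanitised to the
traditional 10-character limit, with collision suffixing).

The packaged fixture (:func:`load_focal_sites_fixture`) transcribes the
13-measurement battery for the seven focal early-Holocene sites of
southern China, Vietnam and Taiwan: five single female crania plus the
Huiyaotian and Liyupo summary samples.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix

from .measurements import CranialSpecimen, Flag, PopulationSample

__all__ = [
    "read_specimen_table",
    "write_specimen_table",
    "read_sample_table",
    "write_sample_table",
    "load_focal_sites_fixture",
    "write_distance_phylip",
    "read_distance_phylip",
    "TableParseError",
]


class TableParseError(ValueError):
    """Raised when a CSV cell or row cannot be interpreted."""


_PAREN = re.compile(r"^\((.+)\)$")
_RESERVED_SPECIMEN_COLS = ("specimen_id", "site", "sex")
_RESERVED_SAMPLE_COLS = ("sample_id", "group_tag")


def _parse_cell(raw: str, row_id: str, code: str) -> tuple[float | None, Flag]:
    cell = raw.strip()
    if not cell:
        return None, Flag.MISSING
    flag = Flag.OBSERVED
    m = _PAREN.match(cell)
    if m:
        cell = m.group(1).strip()
        flag = Flag.ESTIMATED
    try:
        value = float(cell)
    except ValueError:
        raise TableParseError(
            f"row {row_id!r}, column {code}: cannot parse {raw!r} as a measurement"
        ) from None
    return value, flag


def read_specimen_table(path: str | Path) -> list[CranialSpecimen]:
    """Read a specimen CSV into :class:`CranialSpecimen` records."""
    path = Path(path)
    specimens: list[CranialSpecimen] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file")
        codes = [c for c in reader.fieldnames if c not in _RESERVED_SPECIMEN_COLS]
        for row in reader:
            sid = (row.get("specimen_id") or "").strip()
            if not sid:
                raise TableParseError(f"{path}: row without specimen_id")
            if sid in seen:
                raise TableParseError(f"{path}: duplicate specimen_id {sid!r}")
            seen.add(sid)
            values: dict[str, float] = {}
            flags: dict[str, Flag] = {}
            for code in codes:
                value, flag = _parse_cell(row.get(code) or "", sid, code)
                if value is not None:
                    values[code] = value
                    flags[code] = flag
            specimens.append(
                CranialSpecimen(
                    specimen_id=sid,
                    site=(row.get("site") or "").strip(),
                    sex_label=(row.get("sex") or "").strip(),
                    values=values,
                    flags=flags,
                )
            )
    return specimens


def write_specimen_table(
    specimens: Sequence[CranialSpecimen],
    path: str | Path,
    battery: Sequence[str] | None = None,
) -> Path:
    """Write specimens in the parenthesis/empty-cell CSV dialect."""
    path = Path(path)
    if battery is None:
        codes: list[str] = []
        for sp in specimens:
            for c in sp.values:
                if c not in codes:
                    codes.append(c)
    else:
        codes = list(battery)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_RESERVED_SPECIMEN_COLS, *codes])
        for sp in specimens:
            row = [sp.specimen_id, sp.site, sp.sex_label]
            for code in codes:
                if code not in sp.values:
                    row.append("")
                else:
                    text = _fmt(sp.values[code])
                    if sp.flags.get(code) is Flag.ESTIMATED:
                        text = f"({text})"
                    row.append(text)
            writer.writerow(row)
    return path


def _fmt(x: float) -> str:
    return f"{x:g}"


def read_sample_table(path: str | Path) -> list[PopulationSample]:
    """Read a population-sample CSV (``<code>_n/_mean/_sd`` triples)."""
    path = Path(path)
    samples: list[PopulationSample] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file")
        codes: list[str] = []
        for col in reader.fieldnames:
            if col.endswith("_mean"):
                codes.append(col[: -len("_mean")])
        for row in reader:
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise TableParseError(f"{path}: row without sample_id")
            if sid in seen:
                raise TableParseError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            stats: dict[str, tuple[int, float, float | None]] = {}
            for code in codes:
                mean_raw = (row.get(f"{code}_mean") or "").strip()
                if not mean_raw:
                    continue
                try:
                    mean = float(mean_raw)
                    n = int((row.get(f"{code}_n") or "1").strip() or 1)
                    sd_raw = (row.get(f"{code}_sd") or "").strip()
                    sd = float(sd_raw) if sd_raw else None
                except ValueError:
                    raise TableParseError(
                        f"row {sid!r}, column group {code}: malformed n/mean/sd"
                    ) from None
                stats[code] = (n, mean, sd)
            samples.append(
                PopulationSample(
                    sample_id=sid,
                    group_tag=(row.get("group_tag") or "").strip(),
                    stats=stats,
                )
            )
    return samples


def write_sample_table(
    samples: Sequence[PopulationSample],
    path: str | Path,
    battery: Sequence[str] | None = None,
) -> Path:
    """Write population samples; round-trips through :func:`read_sample_table`."""
    path = Path(path)
    if battery is None:
        codes = []
        for s in samples:
            for c in s.stats:
                if c not in codes:
                    codes.append(c)
    else:
        codes = list(battery)
    header = list(_RESERVED_SAMPLE_COLS)
    for code in codes:
        header += [f"{code}_n", f"{code}_mean", f"{code}_sd"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for s in samples:
            row = [s.sample_id, s.group_tag]
            for code in codes:
                if code not in s.stats:
                    row += ["", "", ""]
                else:
                    n, mean, sd = s.stats[code]
                    row += [str(n), _fmt(mean), "" if sd is None else _fmt(sd)]
            writer.writerow(row)
    return path


def load_focal_sites_fixture() -> tuple[list[CranialSpecimen], list[PopulationSample]]:
    """Load the packaged focal-site fixture.

    Returns the five single female crania (Yahuai, Hang Cho, Mai Da
    Dieu, Bau Du, Xiaoma) and the two summary samples (Huiyaotian,
    Liyupo), restricted to the 13-measurement analysis battery.
    Estimated (parenthesised) values carry the ``estimated`` flag; the
    Xiaoma M17 value is the regression-imputed basion-bregma height.
    """
    data = importlib.resources.files("cranionet") / "data"
    with importlib.resources.as_file(data / "focal_sites_specimens.csv") as p:
        specimens = read_specimen_table(p)
    with importlib.resources.as_file(data / "focal_sites_samples.csv") as p:
        samples = read_sample_table(p)
    return specimens, samples


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

def _sanitize_labels(labels: Sequence[str], suffixing: bool = True) -> list[str]:
    out: list[str] = []
    for lab in labels:
        s = re.sub(r"\s+", "_", lab.strip())[:10]
        if s in out:
            if not suffixing:
                raise ValueError(f"PHYLIP label collision on {s!r}")
            k = 1
            while True:
                candidate = f"{s[:10 - len(str(k)) - 1]}_{k}"
                if candidate not in out:
                    s = candidate
                    break
                k += 1
        out.append(s)
    return out


def write_distance_phylip(
    dm: DistanceMatrix, path: str | Path, suffixing: bool = True
) -> Path:
    """Write a labelled distance matrix in PHYLIP square format."""
    path = Path(path)
    labels = _sanitize_labels(list(dm.ids), suffixing=suffixing)
    with path.open("w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for lab, row in zip(labels, dm.data):
            fh.write(lab.ljust(10) + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
    return path


def read_distance_phylip(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix."""
    path = Path(path)
    with path.open() as fh:
        tokens = fh.read().split()
    if not tokens:
        raise TableParseError(f"{path}: empty PHYLIP file")
    n = int(tokens[0])
    pos = 1
    labels: list[str] = []
    rows: list[list[float]] = []
    for _ in range(n):
        labels.append(tokens[pos])
        row = [float(t) for t in tokens[pos + 1: pos + 1 + n]]
        if len(row) != n:
            raise TableParseError(f"{path}: short row for {labels[-1]!r}")
        rows.append(row)
        pos += 1 + n
    mat = np.asarray(rows)
    mat = (mat + mat.T) / 2.0  # guard against asymmetric rounding in the file
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, labels)
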