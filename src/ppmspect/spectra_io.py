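"""Reading and writing of 1D NMR spectra and sample metadata.

All other modules consume only :class:`Spectrum` and :class:`SampleTable`;
nothing downstream parses files. The on-disk spectra-matrix format is a
delimited text table whose first column is the ppm grid and whose remaining
columns are one intensity trace per sample. JCAMP-DX 1D records (AFFN-encoded
XYDATA or NTUPLES real part) are supported read-only for single spectra.

Internal ppm orientation is always ascending; readers normalize descending
grids (the common NMR display convention) on input.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("preterm", "term")

#: relative tolerance on grid-spacing uniformity
_GRID_RTOL = 1e-9


class SpectraIOError(ValueError):
    """Raised for malformed spectra or metadata inputs."""


@dataclass(frozen=True)
class Spectrum:
    """One sample's intensity trace on a strictly increasing uniform ppm grid."""

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise SpectraIOError(
                f"sample {self.sample_id!r}: ppm and intensity must be 1-D "
                f"vectors of equal length (got {ppm.shape} vs {inten.shape})"
            )
        if ppm.size < 2:
            raise SpectraIOError(f"sample {self.sample_id!r}: need at least 2 grid points")
        check_uniform_grid(ppm, context=f"sample {self.sample_id!r}")

    @property
    def step(self) -> float:
        """Grid spacing in ppm."""
        return float(self.ppm[1] - self.ppm[0])

    def __len__(self) -> int:
        return int(self.ppm.size)


def check_uniform_grid(ppm: np.ndarray, context: str = "grid") -> None:
    """Validate that *ppm* is strictly increasing and uniform.

    Raises :class:`SpectraIOError` naming the first offending row index.
    """
    diffs = np.diff(ppm)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise SpectraIOError(
            f"{context}: ppm column not strictly increasing at row {i + 1} "
            f"(ppm[{i}]={ppm[i]!r}, ppm[{i + 1}]={ppm[i + 1]!r})"
        )
    step = diffs[0]
    rel = np.abs(diffs - step) / abs(step)
    bad = np.nonzero(rel > _GRID_RTOL)[0]
    if bad.size:
        i = int(bad[0])
        raise SpectraIOError(
            f"{context}: non-uniform ppm spacing at row {i + 1} "
            f"(step {diffs[i]!r} vs expected {step!r})"
        )


@dataclass
class SampleTable:
    """Sample metadata: unique ids, group labels, optional covariates."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("sample_id", "group"):
            if col not in df.columns:
                raise SpectraIOError(f"sample table missing required column {col!r}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        df["group"] = df["group"].astype(str).str.strip().str.lower()
        unknown = sorted(set(df["group"]) - set(VALID_GROUPS))
        if unknown:
            raise SpectraIOError(
                f"unknown group label(s) {unknown}; expected one of {list(VALID_GROUPS)}"
            )
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dupes:
            raise SpectraIOError(f"duplicate sample ids: {dupes}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Group labels aligned to *sample_ids*; errors list orphans on mismatch."""
        lookup = dict(zip(self.data["sample_id"], self.data["group"]))
        missing = [s for s in sample_ids if s not in lookup]
        extra = sorted(set(lookup) - set(sample_ids))
        if missing or extra:
            raise SpectraIOError(
                "spectra/metadata id mismatch; "
                f"spectra without metadata: {missing}; metadata without spectra: {extra}"
            )
        return np.array([lookup[s] for s in sample_ids])

    def __len__(self) -> int:
        return len(self.data)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_spectra_matrix(path: str | Path) -> list[Spectrum]:
    """Read a spectra-matrix text file: first column ``ppm``, one column per sample.

    The delimiter (tab or comma) is autodetected from the header line. All
    returned spectra share the validated common grid; column order is
    preserved. Missing cells are errors, not NaN-tolerated.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim)
    if df.columns[0].strip().lower() != "ppm":
        raise SpectraIOError(f"{path}: first column must be 'ppm', got {df.columns[0]!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise SpectraIOError(f"{path}: missing/ragged cells at data row(s) {rows}")
    ppm = df.iloc[:, 0].to_numpy(dtype=float)
    if ppm.size >= 2 and ppm[1] < ppm[0]:  # descending convention: flip
        df = df.iloc[::-1].reset_index(drop=True)
        ppm = df.iloc[:, 0].to_numpy(dtype=float)
    check_uniform_grid(ppm, context=str(path))
    return [
        Spectrum(sample_id=str(col), ppm=ppm, intensity=df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]


def write_spectra_matrix(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write spectra to the tab-delimited matrix format (9 significant digits)."""
    if not spectra:
        raise SpectraIOError("no spectra to write")
    ppm = spectra[0].ppm
    for sp in spectra[1:]:
        if sp.ppm.shape != ppm.shape or not np.allclose(sp.ppm, ppm, rtol=0, atol=1e-12):
            raise SpectraIOError(f"sample {sp.sample_id!r} is not on the common grid")
    df = pd.DataFrame({"ppm": ppm})
    for sp in spectra:
        df[sp.sample_id] = sp.intensity
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, 1D AFFN)
# ---------------------------------------------------------------------------

_LDR_RE = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")


def _parse_jcamp_records(text: str) -> list[tuple[str, str]]:
    """Split JCAMP-DX text into (normalized label, content) records."""
    records: list[tuple[str, str]] = []
    label = None
    lines: list[str] = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        m = _LDR_RE.match(line)
        if m:
            if label is not None:
                records.append((label, "\n".join(lines)))
            # labels are case/space/hyphen insensitive per the standard
            label = re.sub(r"[ \-_/]", "", m.group(1)).upper()
            lines = [m.group(2)]
        elif label is not None:
            lines.append(line)
    if label is not None:
        records.append((label, "\n".join(lines)))
    return records


def _affn_values(body: str) -> np.ndarray:
    toks = re.findall(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?", body)
    return np.array([float(t) for t in toks], dtype=float)


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a 1D JCAMP-DX spectrum (AFFN ``XYDATA=(X++(Y..Y))`` or the real
    page of an NTUPLES block).

    The ppm grid is reconstructed from FIRSTX/LASTX/NPOINTS and intensities
    are scaled by YFACTOR. Descending grids (FIRSTX > LASTX, the NMR
    convention) are reversed to ascending with intensities in lockstep.
    """
    path = Path(path)
    records = _parse_jcamp_records(path.read_text())
    rec = dict(records)  # last occurrence wins; fine for required scalars

    data_label = None
    for cand in ("XYDATA", "DATATABLE"):
        if cand in rec:
            data_label = cand
            break
    required = ["FIRSTX", "LASTX", "NPOINTS"]
    missing = [r for r in required if r not in rec]
    if data_label is None:
        missing.append("XYDATA (or NTUPLES DATA TABLE)")
    if missing:
        raise SpectraIOError(f"{path}: missing required JCAMP-DX records: {missing}")

    firstx = float(rec["FIRSTX"])
    lastx = float(rec["LASTX"])
    npoints = int(float(rec["NPOINTS"]))
    yfactor = float(rec.get("YFACTOR", 1.0))

    body_lines = rec[data_label].splitlines()
    # first line of the record is the variable list, e.g. "(X++(Y..Y))"
    y: list[float] = []
    for line in body_lines[1:]:
        vals = _affn_values(line)
        if vals.size == 0:
            continue
        y.extend(vals[1:])  # first value per line is the X check value
    intensity = np.array(y, dtype=float) * yfactor
    if intensity.size != npoints:
        raise SpectraIOError(
            f"{path}: NPOINTS={npoints} but data table holds {intensity.size} ordinates"
        )
    ppm = np.linspace(firstx, lastx, npoints)
    if firstx > lastx:
        ppm = ppm[::-1]
        intensity = intensity[::-1]
    return Spectrum(sample_id=path.stem, ppm=ppm, intensity=intensity)


# ---------------------------------------------------------------------------
# Sample tables and reports
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    """Read a delimited metadata table with at least sample_id and group columns."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    df = pd.read_csv(path, sep=_sniff_delimiter(header))
    df.columns = [c.strip() for c in df.columns]
    return SampleTable(df)


def write_sample_table(path: str | Path, table: SampleTable) -> None:
    table.data.to_csv(path, sep="\t", index=False)


#: Table-2-shaped metric column order used in reports
METRIC_COLUMNS = [
    "model", "accuracy", "f1", "fpr", "fnr", "tpr", "tnr",
]


def write_report(path: str | Path, results: Mapping) -> None:
    """Write an analysis report.

    Emits *path* as structured JSON and, when ``results['metrics']`` holds
    Table-2-shaped rows (mapping with accuracy/f1/fpr/fnr/tpr/tnr per model),
    a sibling ``<stem>_metrics.tsv`` with the six metric columns per model.
    """
    path = Path(path)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if hasattr(obj, "to_report_dict"):
            return obj.to_report_dict()
        raise TypeError(f"unserializable object of type {type(obj)}")

    path.write_text(json.dumps(results, indent=2, default=_default, sort_keys=True) + "\n")

    metrics = results.get("metrics")
    if metrics:
        rows = []
        for row in metrics:
            if hasattr(row, "to_report_dict"):
                row = row.to_report_dict()
            rows.append({c: row.get(c) for c in METRIC_COLUMNS})
        pd.DataFrame(rows, columns=METRIC_COLUMNS).to_csv(
            path.with_name(path.stem + "_metrics.tsv"), sep="\t", index=False,
            float_format="%.4f",
        )
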