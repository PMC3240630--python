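"""Amide cross-peak lists and titration series.

A 2-D 1H-15N HSQC spectrum gives one cross-peak per backbone amide.  A
:class:`PeakList` stores those peaks keyed by residue; a
:class:`TitrationSeries` is an ordered sequence of peak lists, one per
titration point, together with the total protein and ligand concentrations
at each point.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# 15N shifts are downscaled by this factor when combined with 1H shifts so
# that both dimensions contribute comparably to a Euclidean distance.
N15_SCALE = 5.0

_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)N-H$")


@dataclass(frozen=True)
class Peak:
    """One backbone amide cross-peak."""

    shift_H: float  # ppm
    shift_N: float  # ppm
    intensity: float = 1.0
    present: bool = True


class PeakList(dict):
    """Mapping ``(residue_number, residue_type)`` -> :class:`Peak`.

    Residue numbers are unique: inserting a second entry for an already
    present residue number raises ``ValueError``.
    """

    def __setitem__(self, key, value):
        key = (int(key[0]), str(key[1]))
        for k in self:
            if k[0] == key[0] and k != key:
                raise ValueError(f"duplicate residue number {key[0]}")
        super().__setitem__(key, value)

    def residue_numbers(self):
        return sorted(k[0] for k in self)

    def by_number(self, resnum: int) -> Peak:
        for (num, _), peak in self.items():
            if num == resnum:
                return peak
        raise KeyError(resnum)


@dataclass
class TitrationPoint:
    """One titration point: concentrations plus the observed peak list."""

    P_tot_mM: float
    L_tot_mM: float
    peaks: PeakList = field(default_factory=PeakList)


@dataclass
class TitrationSeries:
    """Ordered titration points, typically from zero ligand to saturation."""

    points: list[TitrationPoint] = field(default_factory=list)

    def __len__(self):
        return len(self.points)

    @property
    def reference(self) -> TitrationPoint:
        return self.points[0]

    @property
    def endpoint(self) -> TitrationPoint:
        return self.points[-1]


def read_peak_list(source, dialect: str = "sparky") -> PeakList:
    """Read a single peak list from a text stream or path.

    ``dialect='sparky'`` expects SPARKY ``.list`` rows such as
    ``E408N-H  119.21  8.03  1.0e6`` (w1 = 15N ppm, w2 = 1H ppm, optional
    height).  ``dialect='csv'`` expects columns ``residue, residue_type,
    w1_15N_ppm, w2_1H_ppm[, intensity]``.  Unassigned rows are skipped with
    a warning; malformed rows raise ``ValueError`` with the line number.
    """
    if isinstance(source, (str, bytes, os.PathLike)):
        with open(source) as fh:
            return read_peak_list(fh, dialect=dialect)
    if dialect == "csv":
        return _read_csv_peaks(source)
    if dialect != "sparky":
        raise ValueError(f"unknown peak-list dialect: {dialect!r}")
    peaks = PeakList()
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.lower().startswith(("assignment", "#")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 'assignment w1 w2 [height]', got {line!r}")
        m = _SPARKY_ASSIGNMENT.match(fields[0])
        if m is None:
            logger.warning("line %d: skipping unassigned/unsupported peak %r", lineno, fields[0])
            continue
        restype, resnum = m.group(1).upper(), int(m.group(2))
        try:
            shift_N = float(fields[1])
            shift_H = float(fields[2])
            intensity = float(fields[3]) if len(fields) > 3 else 1.0
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field in {line!r}") from exc
        peaks[(resnum, restype)] = Peak(shift_H=shift_H, shift_N=shift_N, intensity=intensity)
    return peaks


def _read_csv_peaks(source) -> PeakList:
    df = pd.read_csv(source)
    required = {"residue", "w1_15N_ppm", "w2_1H_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV missing columns: {sorted(missing)}")
    peaks = PeakList()
    for _, row in df.iterrows():
        restype = str(row.get("residue_type", "X"))
        peaks[(int(row["residue"]), restype)] = Peak(
            shift_H=float(row["w2_1H_ppm"]),
            shift_N=float(row["w1_15N_ppm"]),
            intensity=float(row.get("intensity", 1.0)),
        )
    return peaks


def write_peak_list(peaks: PeakList, out) -> None:
    """Write a SPARKY-style ``.list`` file."""
    if isinstance(out, (str, bytes, os.PathLike)):
        with open(out, "w") as fh:
            write_peak_list(peaks, fh)
            return
    out.write(f"{'Assignment':>12} {'w1':>8} {'w2':>8} {'Data Height':>12}\n")
    for (resnum, restype) in sorted(peaks):
        p = peaks[(resnum, restype)]
        out.write(f"{restype}{resnum}N-H".rjust(12))
        out.write(f" {p.shift_N:8.3f} {p.shift_H:8.3f} {p.intensity:12.4g}\n")


def series_to_frame(series: TitrationSeries) -> pd.DataFrame:
    """Flatten a titration series to a long-format table."""
    rows = []
    for i, pt in enumerate(series.points):
        for (resnum, restype) in sorted(pt.peaks):
            p = pt.peaks[(resnum, restype)]
            rows.append(
                dict(
                    point=i,
                    residue=resnum,
                    residue_type=restype,
                    w1_15N_ppm=p.shift_N,
                    w2_1H_ppm=p.shift_H,
                    intensity=p.intensity,
                    present=p.present,
                    P_tot_mM=pt.P_tot_mM,
                    L_tot_mM=pt.L_tot_mM,
                )
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> TitrationSeries:
    points = []
    for i, grp in df.groupby("point"):
        peaks = PeakList()
        for _, row in grp.iterrows():
            peaks[(int(row["residue"]), str(row["residue_type"]))] = Peak(
                shift_H=float(row["w2_1H_ppm"]),
                shift_N=float(row["w1_15N_ppm"]),
                intensity=float(row["intensity"]),
                present=bool(row.get("present", True)),
            )
        points.append(
            TitrationPoint(
                P_tot_mM=float(grp["P_tot_mM"].iloc[0]),
                L_tot_mM=float(grp["L_tot_mM"].iloc[0]),
                peaks=peaks,
            )
        )
    return TitrationSeries(points=points)


def read_series_csv(path) -> TitrationSeries:
    return frame_to_series(pd.read_csv(path))


def write_series_csv(series: TitrationSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def scaled_distance(a: Peak, b: Peak) -> float:
    """Euclidean distance in (1H, 15N/5) shift space, in scaled ppm."""
    return float(np.hypot(a.shift_H - b.shift_H, (a.shift_N - b.shift_N) / N15_SCALE))


def match_peaks(series: TitrationSeries, max_step: float = 0.05) -> TitrationSeries:
    """Propagate assignments through a titration by nearest-neighbour tracking.

    Later points whose peaks are unassigned (residue type ``'?'``) inherit
    the assignment of the nearest previous-point peak in the scaled
    (1H, 15N/5) space, provided the move is at most ``max_step`` scaled ppm.
    When two previous peaks claim the same new peak, both stay unmatched
    (dropped from the point).  Fully assigned points pass through unchanged.
    """
    if len(series) < 2:
        raise ValueError("need at least two titration points to match")
    out_points = [series.points[0]]
    for pt in series.points[1:]:
        prev = out_points[-1].peaks
        unassigned = [k for k in pt.peaks if k[1] == "?"]
        if not unassigned:
            out_points.append(pt)
            continue
        assigned_part = {k: v for k, v in pt.peaks.items() if k[1] != "?"}
        claims: dict = {}  # candidate key -> list of previous keys claiming it
        for pkey, ppeak in prev.items():
            if not ppeak.present or pkey in assigned_part:
                continue
            best, best_d = None, np.inf
            for ckey in unassigned:
                d = scaled_distance(ppeak, pt.peaks[ckey])
                if d < best_d:
                    best, best_d = ckey, d
            if best is not None and best_d <= max_step:
                claims.setdefault(best, []).append(pkey)
        new_peaks = PeakList()
        for k, v in assigned_part.items():
            new_peaks[k] = v
        for ckey, claimants in claims.items():
            if len(claimants) > 1:
                logger.warning("ambiguous match: %s claimed by %s; all left unmatched", ckey, claimants)
                continue
            new_peaks[claimants[0]] = replace(pt.peaks[ckey])
        out_points.append(TitrationPoint(P_tot_mM=pt.P_tot_mM, L_tot_mM=pt.L_tot_mM, peaks=new_peaks))
    return TitrationSeries(points=out_points)
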