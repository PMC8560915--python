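"""Radial scan sets and Beckman XL-A-style ASCII file I/O.

A :class:`ScanSet` is an ordered stack of radial signal profiles acquired at
a fixed rotor speed, sharing one radial grid. On disk each scan is one ASCII
file: a free-text description line, a header line

    R <cell:int> <temp_C:float> <rpm:int> <time_s:float> <w2t:float>

and then one ``<radius_cm>\\t<signal>`` row per radial point (radius printed
with 4 decimals, signal with 6). A scan set is a directory of such files or
an explicit ordered file list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ScanSet", "ScanFormatError", "read_scans", "write_scans"]


class ScanFormatError(ValueError):
    """Malformed scan file; message carries the offending file and line."""


@dataclass
class ScanSet:
    """Ordered sedimentation-velocity scans sharing one radial grid.

    Attributes
    ----------
    channel : detection channel name (e.g. ``"fluorescence"``, ``"absorbance"``).
    radii_cm : strictly increasing radii, shared by all scans.
    times_s : strictly increasing scan times.
    signals : array of shape (n_scans, n_radii).
    rpm : rotor speed, constant within a set.
    temperature_C : rotor temperature.
    cell : cell number written to file headers.
    description : free-text first line of each scan file.
    """

    channel: str
    radii_cm: np.ndarray
    times_s: np.ndarray
    signals: np.ndarray
    rpm: float
    temperature_C: float = 20.0
    cell: int = 1
    description: str = "simulated sedimentation velocity scan"
    meniscus_cm: float | None = None

    def __post_init__(self) -> None:
        self.radii_cm = np.asarray(self.radii_cm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if np.any(np.diff(self.radii_cm) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if self.signals.shape != (len(self.times_s), len(self.radii_cm)):
            raise ValueError(
                f"signals shape {self.signals.shape} does not match "
                f"({len(self.times_s)} scans, {len(self.radii_cm)} radii)"
            )
        if self.rpm <= 0:
            raise ValueError("rpm must be positive")

    @property
    def n_scans(self) -> int:
        return len(self.times_s)

    @property
    def omega(self) -> float:
        return self.rpm * 2.0 * math.pi / 60.0

    @property
    def meniscus(self) -> float:
        """Meniscus radius: explicit if set, else the first radial point."""
        return self.meniscus_cm if self.meniscus_cm is not None else float(self.radii_cm[0])

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, ScanSet):
            return NotImplemented
        return (
            self.channel == other.channel
            and self.rpm == other.rpm
            and self.temperature_C == other.temperature_C
            and np.array_equal(self.radii_cm, other.radii_cm)
            and np.array_equal(self.times_s, other.times_s)
            and np.array_equal(self.signals, other.signals)
        )


def write_scans(scanset: ScanSet, directory: str | Path, stem: str = "scan") -> list[Path]:
    """Write one ASCII file per scan into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    omega2 = scanset.omega**2
    paths = []
    for i, t in enumerate(scanset.times_s):
        path = directory / f"{stem}{i + 1:04d}.ra{scanset.cell}"
        with open(path, "w") as fh:
            fh.write(scanset.description + "\n")
            fh.write(
                f"R {scanset.cell} {scanset.temperature_C:.1f} {int(round(scanset.rpm))} "
                f"{t:.1f} {omega2 * t:.6e}\n"
            )
            for r, c in zip(scanset.radii_cm, scanset.signals[i]):
                fh.write(f"{r:.4f}\t{c:.6f}\n")
        paths.append(path)
    return paths


def _parse_scan_file(path: Path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ScanFormatError(f"{path}: fewer than 3 lines")
    header = lines[1].split()
    if len(header) != 6 or header[0] != "R":
        raise ScanFormatError(f"{path}:2: malformed header line {lines[1]!r}")
    try:
        cell = int(header[1])
        temp = float(header[2])
        rpm = int(header[3])
        time_s = float(header[4])
        float(header[5])  # w2t, redundant with rpm*time
    except ValueError as exc:
        raise ScanFormatError(f"{path}:2: {exc}") from exc
    radii, signal = [], []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ScanFormatError(f"{path}:{ln}: expected two columns, got {line!r}")
        try:
            r, c = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ScanFormatError(f"{path}:{ln}: {exc}") from exc
        if radii and r <= radii[-1]:
            raise ScanFormatError(f"{path}:{ln}: radius {r} not increasing")
        radii.append(r)
        signal.append(c)
    return lines[0], cell, temp, rpm, time_s, np.array(radii), np.array(signal)


def read_scans(
    source: str | Path | list, channel: str = "signal", meniscus_cm: float | None = None
) -> ScanSet:
    """Read a scan set from a directory (files sorted by name) or a file list.

    Raises :class:`ScanFormatError` (with file and line) for malformed
    headers, non-increasing radii, or mixed rotor speeds; all scans must
    share the same radial grid.
    """
    if isinstance(source, (str, Path)):
        src = Path(source)
        paths = sorted(p for p in src.iterdir() if p.is_file()) if src.is_dir() else [src]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise ScanFormatError("no scan files found")

    parsed = [_parse_scan_file(p) for p in paths]
    desc, cell, temp, rpm, _, radii0, _ = parsed[0]
    for p, rec in zip(paths, parsed):
        if rec[3] != rpm:
            raise ScanFormatError(f"{p}:2: rotor speed {rec[3]} differs from {rpm}")
        if len(rec[5]) != len(radii0) or not np.array_equal(rec[5], radii0):
            raise ScanFormatError(f"{p}: radial grid differs from first scan")
    order = np.argsort([rec[4] for rec in parsed], kind="stable")
    times = np.array([parsed[i][4] for i in order])
    signals = np.vstack([parsed[i][6] for i in order])
    return ScanSet(
        channel=channel,
        radii_cm=radii0,
        times_s=times,
        signals=signals,
        rpm=rpm,
        temperature_C=temp,
        cell=cell,
        description=desc,
        meniscus_cm=meniscus_cm,
    )
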