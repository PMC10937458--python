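"""Dose-volume histograms: data model, text I/O, conversions and dose metrics.

A DVH is a list of (dose, volume) bins over a target structure.  Two kinds
are supported: *differential* (fractional volume at each dose; volumes sum
to 1) and *cumulative* (fractional volume receiving at least each dose;
non-increasing from 1).  Each differential bin is treated as a point mass
at its stated dose.

The text format is a single dialect::

    # kind=differential unit=Gy-w target=GTV1
    dose,volume
    10.0,0.2
    ...

Doses may be BNCT weighted dose (unit ``Gy-w``) or photon-equivalent dose
(unit ``Gy``); downstream code checks the unit tag rather than guessing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "DVH",
    "DVHParseError",
    "read_dvh",
    "write_dvh",
    "to_differential",
    "to_cumulative",
    "min_dose",
    "max_dose",
    "mean_dose",
    "volume_fraction_below",
    "dose_at_volume",
]

logger = logging.getLogger(__name__)

KINDS = ("differential", "cumulative")
DOSE_UNITS = ("Gy-w", "Gy")

#: differential volumes may sum to within this of 1 and are renormalized
VOLUME_SUM_TOL = 0.01
_ZERO_VOLUME = 1e-12


class DVHParseError(ValueError):
    pass


@dataclass(frozen=True)
class DVH:
    """Binned dose-volume histogram over one target structure."""

    kind: str
    doses: np.ndarray
    volumes: np.ndarray
    dose_unit: str = "Gy-w"
    target_label: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.dose_unit not in DOSE_UNITS:
            raise ValueError(f"dose_unit must be one of {DOSE_UNITS}")
        doses = np.atleast_1d(np.asarray(self.doses, dtype=float))
        vols = np.atleast_1d(np.asarray(self.volumes, dtype=float))
        if doses.shape != vols.shape or doses.ndim != 1 or doses.size == 0:
            raise ValueError("doses and volumes must be equal-length 1-D arrays")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(vols < -_ZERO_VOLUME):
            raise ValueError("volumes must be non-negative")
        vols = np.clip(vols, 0.0, None)
        if self.kind == "differential":
            total = vols.sum()
            if not (1 - VOLUME_SUM_TOL <= total <= 1 + VOLUME_SUM_TOL):
                raise ValueError(
                    f"differential volumes sum to {total:.4f}, outside "
                    f"[{1 - VOLUME_SUM_TOL}, {1 + VOLUME_SUM_TOL}]"
                )
            if abs(total - 1) > 1e-12:
                logger.debug("renormalizing differential DVH (sum=%.6f)", total)
                vols = vols / total
        else:
            if np.any(np.diff(vols) > 1e-9):
                raise ValueError("cumulative volumes must be non-increasing")
            if not (1 - VOLUME_SUM_TOL <= vols[0] <= 1 + VOLUME_SUM_TOL):
                raise ValueError(
                    f"cumulative DVH must start at volume 1 (got {vols[0]:.4f})"
                )
            if abs(vols[0] - 1) > 1e-12:
                logger.debug("renormalizing cumulative DVH (v[0]=%.6f)", vols[0])
                vols = vols / vols[0]
            vols = np.minimum.accumulate(vols)  # clean 1e-9-scale wiggles
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "volumes", vols)

    def __len__(self):
        return self.doses.size

    # convenience method forms of the module-level operations
    def to_differential(self) -> "DVH":
        return to_differential(self)

    def to_cumulative(self) -> "DVH":
        return to_cumulative(self)

    @property
    def min_dose(self) -> float:
        return min_dose(self)

    @property
    def max_dose(self) -> float:
        return max_dose(self)

    @property
    def mean_dose(self) -> float:
        return mean_dose(self)


def to_differential(dvh: DVH) -> DVH:
    """Convert to a differential DVH by successive differencing.

    The volume beyond the last listed dose is attributed to the last bin.
    Returns a copy if already differential.
    """
    if dvh.kind == "differential":
        return replace(dvh)
    v = dvh.volumes
    diff = np.append(v[:-1] - v[1:], v[-1])
    return DVH(
        kind="differential",
        doses=dvh.doses,
        volumes=diff,
        dose_unit=dvh.dose_unit,
        target_label=dvh.target_label,
    )


def to_cumulative(dvh: DVH) -> DVH:
    """Convert to a cumulative (volume receiving >= dose) DVH by suffix sums."""
    if dvh.kind == "cumulative":
        return replace(dvh)
    cum = np.cumsum(dvh.volumes[::-1])[::-1]
    return DVH(
        kind="cumulative",
        doses=dvh.doses,
        volumes=cum,
        dose_unit=dvh.dose_unit,
        target_label=dvh.target_label,
    )


def min_dose(dvh: DVH) -> float:
    """Lowest dose carrying nonzero differential volume."""
    d = to_differential(dvh)
    nz = d.volumes > _ZERO_VOLUME
    if not nz.any():
        raise ValueError("DVH has no nonzero-volume bins")
    return float(d.doses[nz][0])


def max_dose(dvh: DVH) -> float:
    """Highest dose carrying nonzero differential volume."""
    d = to_differential(dvh)
    nz = d.volumes > _ZERO_VOLUME
    if not nz.any():
        raise ValueError("DVH has no nonzero-volume bins")
    return float(d.doses[nz][-1])


def mean_dose(dvh: DVH) -> float:
    """Volume-weighted mean dose, sum(v_i * D_i)."""
    d = to_differential(dvh)
    return float(np.sum(d.volumes * d.doses))


def volume_fraction_below(dvh: DVH, threshold: float) -> float:
    """Fraction of the volume receiving strictly less than ``threshold``."""
    d = to_differential(dvh)
    return float(d.volumes[d.doses < threshold].sum())


def dose_at_volume(dvh: DVH, volume_fraction: float) -> float:
    """Largest dose D such that the cumulative volume at D is >= the given
    fraction, with linear interpolation between cumulative points (the D_v
    coverage metric, e.g. D80 at volume_fraction=0.8)."""
    if not (0 < volume_fraction <= 1):
        raise ValueError("volume_fraction must lie in (0, 1]")
    c = to_cumulative(dvh)
    d, v = c.doses, c.volumes
    idx = np.nonzero(v >= volume_fraction)[0]
    if idx.size == 0:  # can only happen for fractions > v[0] = 1
        raise ValueError("requested volume fraction exceeds total volume")
    i = idx[-1]
    if i == len(d) - 1:
        return float(d[-1])
    drop = v[i] - v[i + 1]
    if drop <= _ZERO_VOLUME:
        return float(d[i])
    return float(d[i] + (d[i + 1] - d[i]) * (v[i] - volume_fraction) / drop)


# ---------------------------------------------------------------------------
# text I/O


def _parse_header(line: str, lineno: int) -> dict:
    body = line.lstrip("#").strip()
    fields = {}
    for token in body.split():
        if "=" not in token:
            raise DVHParseError(f"line {lineno}: malformed header token {token!r}")
        key, _, val = token.partition("=")
        fields[key] = val
    for key in ("kind", "unit"):
        if key not in fields:
            raise DVHParseError(f"line {lineno}: header missing {key}=")
    if fields["kind"] not in KINDS:
        raise DVHParseError(f"line {lineno}: unknown kind {fields['kind']!r}")
    if fields["unit"] not in DOSE_UNITS:
        raise DVHParseError(f"line {lineno}: unknown unit {fields['unit']!r}")
    return fields


def read_dvh(source: Union[str, Path, io.TextIOBase]) -> DVH:
    """Read a DVH from the package text format (see module docstring)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    header = None
    doses, volumes = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if header is None and "=" in line:
                header = _parse_header(line, lineno)
            continue
        if header is None:
            raise DVHParseError(f"line {lineno}: data before '# kind=... unit=...' header")
        if line.lower().replace(" ", "") in ("dose,volume", "dose\tvolume"):
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
        if len(parts) != 2:
            raise DVHParseError(f"line {lineno}: expected 'dose,volume', got {line!r}")
        try:
            doses.append(float(parts[0]))
            volumes.append(float(parts[1]))
        except ValueError as err:
            raise DVHParseError(f"line {lineno}: {err}") from None
    if header is None:
        raise DVHParseError("no header line found")
    if not doses:
        raise DVHParseError("no data rows found")
    try:
        return DVH(
            kind=header["kind"],
            doses=np.array(doses),
            volumes=np.array(volumes),
            dose_unit=header["unit"],
            target_label=header.get("target", ""),
        )
    except ValueError as err:
        raise DVHParseError(str(err)) from None


def write_dvh(dvh: DVH, sink: Union[str, Path, io.TextIOBase]) -> None:
    """Write a DVH in the package text format (read_dvh round-trips it)."""
    header = f"# kind={dvh.kind} unit={dvh.dose_unit}"
    if dvh.target_label:
        header += f" target={dvh.target_label}"
    rows = [header, "dose,volume"]
    rows += [f"{d:.12g},{v:.12g}" for d, v in zip(dvh.doses, dvh.volumes)]
    text = "\n".join(rows) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
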