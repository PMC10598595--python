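"""Electrode montages on the unit sphere.

The analysis operates on a 20-channel 10-20 montage (the channel space that
remains after peripheral electrodes of a dense infant net are dropped and the
layout is converted to the international 10-20 system).  Positions live on the
unit sphere with x pointing to the right preauricular point, y to the nasion
and z to the vertex; spherical-spline interpolation and the surface Laplacian
only ever consume the cosine of inter-electrode angles, so the radius is
irrelevant beyond normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "standard_1020", "DEFAULT_CHANNELS"]

#: The 20-name 10-20 set used throughout (includes every electrode named in
#: the result tables: C3, P4, Pz, Cz, P3, F7, T7, T8, P7, F8, P8, O1, O2, Oz).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


class MontageError(ValueError):
    """Raised for malformed montages (duplicate names, off-sphere positions)."""


@dataclass(frozen=True)
class Montage:
    """Named electrode set with unit-sphere positions.

    Parameters
    ----------
    channels
        Unique channel names.
    positions
        Array of shape ``(n_channels, 3)``; every row must have unit norm.
    """

    channels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channels)
        object.__setattr__(self, "channels", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise MontageError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        if len(set(names)) != len(names):
            raise MontageError("duplicate channel names in montage")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.channels)

    def index(self, names) -> np.ndarray:
        """Indices of ``names`` in channel order; unknown names raise KeyError."""
        lookup = {c: i for i, c in enumerate(self.channels)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"channel {exc.args[0]!r} not in montage") from None

    def subset(self, names) -> "Montage":
        idx = self.index(names)
        return Montage(tuple(names), self.positions[idx])

    def cosine_angles(self) -> np.ndarray:
        """Matrix of cos(angle) between every electrode pair (clipped to [-1, 1])."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)

    # ---- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {c: list(map(float, p)) for c, p in zip(self.channels, self.positions)}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False))

    @classmethod
    def from_json(cls, path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload)
        pos = []
        for name in names:
            entry = payload[name]
            if entry is None or len(entry) != 3:
                raise MontageError(f"montage entry for channel {name!r} is not an x,y,z triple")
            pos.append(entry)
        return cls(names, np.asarray(pos, dtype=float))


def _sph(incl_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector from inclination (from vertex) and azimuth (from +x, toward +y)."""
    th = np.deg2rad(incl_deg)
    ph = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` along the great circle from ``a`` to ``b``."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    v = (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)
    return v / np.linalg.norm(v)


def standard_1020(channels=DEFAULT_CHANNELS) -> Montage:
    """Idealized 10-20 montage on the unit sphere.

    Midline and temporal electrodes follow the classical 10/20 arc fractions
    (nasion-inion and ear-to-ear arcs of 180 deg through the vertex, outer ring
    on the 10% circumference line); F3/F4 and P3/P4 sit at the great-circle
    midpoints of their neighbours, which is how the 10-20 system defines them.
    """
    ring = 72.0  # inclination of the 10% circumference ring
    base = {
        "Fpz": _sph(ring, 90), "Fz": _sph(36, 90), "Cz": _sph(0, 0),
        "Pz": _sph(36, 270), "Oz": _sph(ring, 270),
        "T7": _sph(ring, 180), "C3": _sph(36, 180),
        "C4": _sph(36, 0), "T8": _sph(ring, 0),
        "Fp1": _sph(ring, 108), "F7": _sph(ring, 144),
        "P7": _sph(ring, 216), "O1": _sph(ring, 252),
        "Fp2": _sph(ring, 72), "F8": _sph(ring, 36),
        "P8": _sph(ring, 324), "O2": _sph(ring, 288),
    }
    base["F3"] = _slerp(base["F7"], base["Fz"], 0.5)
    base["F4"] = _slerp(base["F8"], base["Fz"], 0.5)
    base["P3"] = _slerp(base["P7"], base["Pz"], 0.5)
    base["P4"] = _slerp(base["P8"], base["Pz"], 0.5)
    missing = [c for c in channels if c not in base]
    if missing:
        raise MontageError(f"no standard 10-20 position for channel(s) {missing}")
    pos = np.stack([base[c] for c in channels])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(channels), pos)
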