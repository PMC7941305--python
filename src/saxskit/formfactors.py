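"""Atomic X-ray form factors: wavelength-independent f0(s) and anomalous f'(E), f''(E).

The effective form factor near an absorption edge is

    f(s, E) = f0(s) + f'(E) + i f''(E)

with f0 the Cromer-Mann sum-of-Gaussians parameterization (International Tables
vol. C, table 6.1.1.4, as embedded in gemmi's IT92 tables) evaluated at
``stol2 = (s / 4 pi)^2``, and the anomalous corrections either interpolated from a
user-supplied (energy, f', f'') ASCII table or computed by the Cromer-Liberman
algorithm (gemmi's implementation) for elements Ca..U at 1.0-29.4 keV.

At an edge f' dips negative, so |f| < f0: the atom scatters less — the basis of
anomalous-difference SAXS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import gemmi

__all__ = [
    "AnomalousTable",
    "read_anomalous_table",
    "f0",
    "electron_count",
    "anomalous_terms",
    "effective_f",
    "BUILTIN_ENERGY_RANGE_EV",
    "BUILTIN_Z_RANGE",
]

#: energy validity range of the built-in anomalous corrections, eV
BUILTIN_ENERGY_RANGE_EV = (1000.0, 29400.0)
#: element range of the built-in anomalous corrections (Ca..U)
BUILTIN_Z_RANGE = (20, 92)


@dataclass(frozen=True)
class AnomalousTable:
    """Per-element anomalous corrections on an energy grid.

    ``energies`` are strictly increasing (eV); ``f1`` holds f' and ``f2`` holds
    f'' (electrons), with f'' >= 0.
    """

    element: str
    energies: np.ndarray
    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float).ravel()
        f1 = np.asarray(self.f1, dtype=float).ravel()
        f2 = np.asarray(self.f2, dtype=float).ravel()
        if not (e.size == f1.size == f2.size) or e.size < 1:
            raise ValueError("table columns must be non-empty and equal length")
        if e.size > 1 and np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(f2 < 0):
            raise ValueError("f'' must be >= 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "f1", f1)
        object.__setattr__(self, "f2", f2)


def read_anomalous_table(path, element: str) -> AnomalousTable:
    """Read an ASCII anomalous-correction table.

    Rows are ``energy_eV  f_prime  f_doubleprime`` ('#'-comments skipped); a
    2-column file is read as (energy, f') with f'' taken as zero.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError:
                continue
    if not rows:
        raise ValueError(f"{path}: no numeric rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    f2 = data[:, 2] if ncol >= 3 else np.zeros(len(data))
    return AnomalousTable(element=element, energies=data[:, 0],
                          f1=data[:, 1], f2=f2)


def _element(symbol: str) -> gemmi.Element:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unsupported element {symbol!r}")
    return el


def electron_count(element: str) -> int:
    """Atomic number Z (= electron count of the neutral atom)."""
    return _element(element).atomic_number


def f0(element: str, s) -> np.ndarray:
    """Wavelength-independent form factor f0 at momentum transfer ``s`` (1/A).

    Evaluated from the Cromer-Mann 4-Gaussian-plus-constant coefficients:
    ``f0 = c + sum_i a_i exp(-b_i (s/4pi)^2)``; f0(0) equals Z to within 0.1 e.
    """
    el = _element(element)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be >= 0")
    cm = el.it92
    if cm is None:
        raise ValueError(f"no form-factor coefficients for {element!r}")
    a = np.asarray(cm.a, dtype=float)
    b = np.asarray(cm.b, dtype=float)
    stol2 = (s / (4.0 * np.pi)) ** 2
    return cm.c + np.sum(a * np.exp(-np.outer(stol2, b)), axis=-1).reshape(s.shape)


def anomalous_terms(element: str, energy_ev: float,
                    table: AnomalousTable | None = None) -> tuple[float, float]:
    """Anomalous corrections (f', f'') at ``energy_ev``.

    A user table overrides the built-in source and is linearly interpolated on
    its energy grid (exact at the nodes); querying outside the grid is an
    error.  The built-in source is the Cromer-Liberman computation, valid for
    elements Ca..U and energies 1.0-29.4 keV.
    """
    if table is not None:
        if table.element.capitalize() != element.capitalize():
            raise ValueError(
                f"table is for {table.element!r}, not {element!r}")
        e = table.energies
        if not (e[0] <= energy_ev <= e[-1]):
            raise ValueError(
                f"energy {energy_ev} eV outside table range [{e[0]}, {e[-1]}]")
        return (float(np.interp(energy_ev, e, table.f1)),
                float(np.interp(energy_ev, e, table.f2)))
    z = electron_count(element)
    lo_z, hi_z = BUILTIN_Z_RANGE
    if not (lo_z <= z <= hi_z):
        raise ValueError(
            f"built-in anomalous corrections cover Ca..U (Z {lo_z}-{hi_z}); "
            f"{element} (Z={z}) needs a user table")
    lo_e, hi_e = BUILTIN_ENERGY_RANGE_EV
    if not (lo_e <= energy_ev <= hi_e):
        raise ValueError(
            f"energy {energy_ev} eV outside built-in range [{lo_e}, {hi_e}]")
    f1, f2 = gemmi.cromer_liberman(z=z, energy=float(energy_ev))
    return float(f1), float(f2)


def effective_f(element: str, s, energy_ev: float | None = None,
                table: AnomalousTable | None = None) -> np.ndarray:
    """Complex effective form factor f0(s) + f'(E) + i f''(E).

    With ``energy_ev`` absent the result is purely real and equals f0.
    """
    base = f0(element, s).astype(complex)
    if energy_ev is None:
        return base
    f1, f2 = anomalous_terms(element, energy_ev, table)
    return base + (f1 + 1j * f2)
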