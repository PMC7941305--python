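"""Readers and writers for 1D scattering curves, atomic coordinates and detector images.

The universal 1D currency is :class:`ScatteringCurve`: momentum transfer
``s = 4*pi*sin(theta)/lambda`` (internally always in 1/Angstrom), intensity and an
optional per-point error estimate.  Coordinate files (PDB and the atom_site subset
of mmCIF) are parsed through gemmi into the minimal :class:`AtomSet` that the
intensity calculator needs: element labels, positions and occupancies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AtomSet",
    "ScatteringCurve",
    "read_curve",
    "write_curve",
    "read_atoms",
    "cif_to_pdb",
    "read_image",
    "write_image",
]

#: accepted unit dialects for s; internal storage is always 1/Angstrom
S_UNITS = ("1/A", "1/nm")

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "D2O"}


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1D scattering curve (s, I, sigma).

    Parameters
    ----------
    s : array
        Momentum transfer, strictly increasing, in 1/Angstrom.
    I : array
        Intensities, finite, same length as ``s``.
    sigma : array or None
        Optional per-point error estimates, non-negative.
    scale : str
        ``"relative"`` (arbitrary units, e.g. electrons^2) or ``"absolute"``
        (cm^-1 per mg/ml, the .abs convention).
    """

    s: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    scale: str = "relative"
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "I", I)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("curve needs at least 2 points")
        if I.shape != s.shape:
            raise ValueError("s and I must have the same length")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(I)):
            raise ValueError("s and I must be finite")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s must be strictly increasing")
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            if sig.shape != s.shape:
                raise ValueError("sigma length mismatch")
            if np.any(~np.isfinite(sig)) or np.any(sig < 0):
                raise ValueError("sigma must be finite and >= 0")
            object.__setattr__(self, "sigma", sig)
        if self.scale not in ("relative", "absolute"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n(self) -> int:
        return self.s.size

    def interp(self, s: np.ndarray) -> np.ndarray:
        """Linear interpolation of I onto ``s`` (no extrapolation guard)."""
        return np.interp(np.asarray(s, dtype=float), self.s, self.I)

    def with_(self, **kw) -> "ScatteringCurve":
        return replace(self, **kw)


@dataclass(frozen=True)
class AtomSet:
    """Element-labelled 3D coordinates with occupancies, in Angstrom."""

    elements: tuple[str, ...]
    coords: np.ndarray          # (n, 3)
    occupancy: np.ndarray       # (n,)
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        occ = np.asarray(self.occupancy, dtype=float).ravel()
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) != coords.shape[0] or occ.size != coords.shape[0]:
            raise ValueError("elements, coords and occupancy must agree in length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if np.any(occ < 0) or np.any(occ > 1):
            raise ValueError("occupancy must lie in [0, 1]")

    def __len__(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# 1D curves: 3-column whitespace ASCII (.dat / .abs)
# ---------------------------------------------------------------------------

def _to_internal_s(s: np.ndarray, s_unit: str) -> np.ndarray:
    if s_unit not in S_UNITS:
        raise ValueError(f"unknown s unit {s_unit!r}; expected one of {S_UNITS}")
    # 1 nm^-1 = 0.1 A^-1 -- exact factor-of-10 bijection
    return s * 0.1 if s_unit == "1/nm" else s


def read_curve(path, s_unit: str = "1/A", scale: str | None = None) -> ScatteringCurve:
    """Read a whitespace-separated 3-column (s, I[, sigma]) ASCII file.

    Header and comment lines (anything whose leading token is not numeric) are
    skipped.  Rows with two columns yield a curve without error estimates.
    ``s_unit`` names the dialect of the file; values are converted to 1/A.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue
            rows.append(vals)
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 numeric rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    s = _to_internal_s(data[:, 0], s_unit)
    sigma = data[:, 2] if ncol >= 3 else None
    if scale is None:
        scale = "absolute" if path.suffix.lower() == ".abs" else "relative"
    return ScatteringCurve(s=s, I=data[:, 1], sigma=sigma, scale=scale,
                           label=path.name)


def write_curve(curve: ScatteringCurve, path, kind: str = "dat") -> None:
    """Write a curve as 3-column ASCII with 6 significant digits.

    ``kind="abs"`` asserts the absolute-scale convention and requires
    ``curve.scale == "absolute"``.
    """
    if kind not in ("dat", "abs"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "abs" and curve.scale != "absolute":
        raise ValueError("kind='abs' requires an absolute-scale curve")
    with open(path, "w") as fh:
        fh.write(f"# saxskit curve  scale={curve.scale}  unit=1/A\n")
        fh.write("#       s              I              sigma\n")
        for i in range(curve.n):
            line = f"{curve.s[i]:.6e} {curve.I[i]:15.6e}"
            if curve.sigma is not None:
                line += f" {curve.sigma[i]:15.6e}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Coordinates: PDB / mmCIF via gemmi
# ---------------------------------------------------------------------------

def _structure_to_atomset(structure, exclude_waters: bool, label: str) -> AtomSet:
    import gemmi

    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    occ: list[float] = []
    if len(structure) == 0:
        raise ValueError(f"{label}: no models found")
    model = structure[0]  # first model only
    for chain in model:
        for residue in chain:
            if exclude_waters and residue.name.strip().upper() in _WATER_RESNAMES:
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                el = atom.element.name
                if not el or el == "X":
                    raise ValueError(
                        f"{label}: unknown element for atom {atom.name!r}")
                elements.append(el)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                o = atom.occ
                occ.append(1.0 if o is None or o <= 0 else min(o, 1.0))
    if not elements:
        raise ValueError(f"{label}: no atoms found")
    return AtomSet(elements=tuple(elements), coords=np.array(coords),
                   occupancy=np.array(occ), label=label)


def read_atoms(path, format: str | None = None,
               exclude_waters: bool = False) -> AtomSet:
    """Read ATOM/HETATM (PDB) or atom_site (mmCIF) records into an AtomSet.

    ``format`` is ``"pdb"`` or ``"mmcif"``; by default it is inferred from the
    file suffix.  Only the first model is read; alternate locations other than
    blank/'A' are dropped; blank occupancies default to 1.
    """
    import gemmi

    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown coordinate format {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc
    structure.setup_entities()
    return _structure_to_atomset(structure, exclude_waters, path.name)


_PDB_ATOM_FMT = ("ATOM  {serial:5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
                 "{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                 "          {element:>2s}\n")


def cif_to_pdb(cif_path, pdb_path) -> None:
    """Convert an mmCIF structure file to fixed-column PDB.

    Atom count, elements and coordinates (to 3 decimals) are preserved.  Serial
    numbers beyond 99999 are renumbered modulo 99999 with a warning; records
    whose coordinates overflow the 8.3f PDB columns are skipped with a warning.
    """
    import gemmi

    structure = gemmi.read_structure(str(cif_path), format=gemmi.CoorFormat.Mmcif)
    if len(structure) == 0:
        raise ValueError(f"{cif_path}: no models found")
    model = structure[0]
    serial = 0
    wrapped = False
    n_written = 0
    with open(pdb_path, "w") as fh:
        fh.write(f"REMARK   converted from mmCIF by saxskit\n")
        for chain in model:
            chain_id = (chain.name or "A")[:1]
            for ir, residue in enumerate(chain, start=1):
                resseq = residue.seqid.num if residue.seqid.num else ir
                for atom in residue:
                    x, y, z = atom.pos.x, atom.pos.y, atom.pos.z
                    if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999
                            and -999.999 <= z <= 9999.999):
                        warnings.warn(
                            f"atom {atom.name} coordinates overflow PDB columns; "
                            "record skipped")
                        continue
                    serial += 1
                    out_serial = serial
                    if out_serial > 99999:
                        out_serial = (out_serial - 1) % 99999 + 1
                        if not wrapped:
                            warnings.warn("atom serials exceed 99999; "
                                          "renumbering modulo 99999")
                            wrapped = True
                    name = atom.name
                    # PDB column convention: 1-2 char elements start in col 13
                    pname = f" {name}" if len(name) < 4 and len(atom.element.name) == 1 else name
                    altloc = atom.altloc if atom.altloc not in ("", "\x00") else " "
                    fh.write(_PDB_ATOM_FMT.format(
                        serial=out_serial, name=pname[:4], altloc=altloc,
                        res=residue.name[:3], chain=chain_id,
                        resseq=int(resseq) % 10000, x=x, y=y, z=z,
                        occ=atom.occ if atom.occ else 1.0, b=atom.b_iso,
                        element=atom.element.name[:2]))
                    n_written += 1
        fh.write("END\n")
    if n_written == 0:
        raise ValueError(f"{cif_path}: no atoms found")


# ---------------------------------------------------------------------------
# Detector images: TIFF (single frames) and HDF5 (frames or stacks)
# ---------------------------------------------------------------------------

def write_image(image, path) -> None:
    """Write a DetectorImage as TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5).

    The geometry travels in the TIFF ImageDescription tag as JSON, or as HDF5
    attributes; the mask and optional normalisation grid are stored alongside.
    """
    from .detector_sim import DetectorImage  # local import to avoid a cycle

    path = Path(path)
    meta = {
        "pixel_size": image.geometry.pixel_size,
        "distance": image.geometry.distance,
        "wavelength": image.geometry.wavelength,
        "beam_center": list(image.geometry.beam_center),
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.counts.astype(np.uint32),
                         description=json.dumps(meta))
        # mask/norm ride along as extra pages only when informative
        if not image.mask.all() or image.norm is not None:
            warnings.warn("TIFF output stores counts only; use HDF5 to keep "
                          "mask and normalisation")
    elif path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("counts", data=image.counts.astype(np.uint32))
            h5.create_dataset("mask", data=image.mask.astype(np.uint8))
            if image.norm is not None:
                h5.create_dataset("norm", data=image.norm)
            for k, v in meta.items():
                h5.attrs[k] = v
    else:
        raise ValueError(f"unknown image format for {path.name}")


def read_image(path, geometry=None):
    """Read a DetectorImage written by :func:`write_image`."""
    from .detector_sim import DetectorGeometry, DetectorImage

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            counts = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = None
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            pass
        mask = np.ones_like(counts, dtype=bool)
        norm = None
    elif path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as h5:
            counts = h5["counts"][()]
            mask = h5["mask"][()].astype(bool) if "mask" in h5 else \
                np.ones_like(counts, dtype=bool)
            norm = h5["norm"][()] if "norm" in h5 else None
            meta = {k: h5.attrs[k] for k in h5.attrs}
    else:
        raise ValueError(f"unknown image format for {path.name}")
    if geometry is None:
        if not meta:
            raise ValueError(f"{path.name}: no geometry metadata; pass geometry=")
        geometry = DetectorGeometry(
            shape=counts.shape, pixel_size=float(meta["pixel_size"]),
            distance=float(meta["distance"]), wavelength=float(meta["wavelength"]),
            beam_center=tuple(np.asarray(meta["beam_center"], dtype=float)))
    return DetectorImage(counts=counts.astype(np.int64), geometry=geometry,
                         mask=mask, norm=norm)
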