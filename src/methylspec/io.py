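"""Domain types and file I/O for the analysis pipeline.

The pipeline touches four plain-text formats:

* multi-frame XYZ trajectories of the active-site subsystem,
* MODEL/ENDMDL-delimited PDB snapshots,
* whitespace-delimited umbrella-window time series (last column = the
  reaction coordinate R in Å),
* CSV tables and grids on output, plus a JSON run manifest with SHA-256
  checksums.

Atom roles (Sδ, CM, Nζ, the three Nζ substituents, optional H-bond
partners) are bound to file atoms by a :class:`RoleMap` of selectors;
bonds are declared, never inferred.  Selectors match the atom *name*
case-insensitively; the form ``"RES/NAME"`` additionally constrains the
residue name (useful for PDB input, where several residues may share
atom names).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDataError,
    FormatError,
    ParameterError,
    ParseError,
    RoleResolutionError,
)

__all__ = [
    "AtomRecord",
    "RoleMap",
    "Frame",
    "FrameSeries",
    "UmbrellaWindow",
    "read_frames",
    "write_frames",
    "read_window_series",
    "write_window_series",
    "write_results",
]


@dataclass(frozen=True)
class AtomRecord:
    """One labeled atom: name, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    residue: str = ""  # residue name; empty for XYZ input

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ParameterError(f"atom position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ParameterError(f"atom {self.name!r} has non-finite coordinates")
        if not self.element:
            raise ParameterError(f"atom {self.name!r} has an empty element symbol")
        object.__setattr__(self, "position", pos)


def _selector_matches(selector: str, atom: AtomRecord) -> bool:
    if "/" in selector:
        res, name = selector.split("/", 1)
        return atom.residue.upper() == res.upper() and atom.name.upper() == name.upper()
    return atom.name.upper() == selector.upper()


@dataclass(frozen=True)
class RoleMap:
    """Binds the chemistry roles of the SN2 transfer to file atoms.

    ``s_delta`` is the AdoMet sulfur, ``c_methyl`` the transferable
    methyl carbon, ``n_zeta`` the lysine ε-amino nitrogen, and
    ``n_substituents`` its exactly three substituents (Cε plus the
    remaining H / methyl-carbon positions, per methylation state).
    ``extra`` holds optional named selections, e.g. H-bond donors and
    acceptors.
    """

    s_delta: str
    c_methyl: str
    n_zeta: str
    n_substituents: tuple[str, str, str]
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.n_substituents) != 3:
            raise ParameterError(
                f"n_substituents must name exactly 3 atoms, got {len(self.n_substituents)}"
            )
        object.__setattr__(self, "n_substituents", tuple(self.n_substituents))
        object.__setattr__(self, "extra", dict(self.extra))

    def required_roles(self) -> dict[str, str]:
        roles = {
            "s_delta": self.s_delta,
            "c_methyl": self.c_methyl,
            "n_zeta": self.n_zeta,
        }
        for i, sel in enumerate(self.n_substituents, start=1):
            roles[f"n_substituent_{i}"] = sel
        return roles

    def resolve(self, frame: "Frame", role: str, selector: str | None = None) -> AtomRecord:
        """Resolve ``role`` to exactly one atom of ``frame``.

        Raises :class:`RoleResolutionError` naming the role and frame when
        zero or several atoms match.
        """
        if selector is None:
            known = self.required_roles()
            if role in known:
                selector = known[role]
            elif role in self.extra:
                selector = self.extra[role]
            else:
                raise RoleResolutionError(f"unknown role {role!r}")
        matches = [a for a in frame.atoms if _selector_matches(selector, a)]
        if len(matches) != 1:
            raise RoleResolutionError(
                f"role {role!r} (selector {selector!r}) matched {len(matches)} atoms "
                f"in frame {frame.index}; exactly one is required"
            )
        return matches[0]


@dataclass(frozen=True)
class Frame:
    """One snapshot: ordinal index, optional time stamp (ps), atoms."""

    index: int
    atoms: tuple[AtomRecord, ...]
    time: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))

    def positions(self) -> np.ndarray:
        return np.stack([a.position for a in self.atoms])


@dataclass(frozen=True)
class FrameSeries:
    """An ordered, role-mapped trajectory of the active-site subsystem."""

    frames: tuple[Frame, ...]
    role_map: RoleMap
    temperature: float = 283.15  # K

    def __post_init__(self):
        frames = tuple(self.frames)
        if not frames:
            raise ParameterError("FrameSeries requires at least one frame")
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be > 0 K, got {self.temperature}")
        n = len(frames[0].atoms)
        for f in frames:
            if len(f.atoms) != n:
                raise FormatError(
                    f"inconsistent atom count: frame {f.index} has {len(f.atoms)}, expected {n}"
                )
        idx = [f.index for f in frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ParameterError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def validate_roles(self) -> None:
        """Check every required role resolves in every frame."""
        for frame in self.frames:
            for role, sel in self.role_map.required_roles().items():
                self.role_map.resolve(frame, role, sel)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: harmonic bias on R plus its sampled series.

    The bias energy convention is w(R) = k·(R − center)² with NO ½
    prefactor (the CHARMM umbrella convention; force constants in
    kcal mol⁻¹ Å⁻²).  Solvers accept ``half_k=True`` to reinterpret k
    under the conventional ½k(R − center)² form instead.
    """

    center: float  # Å
    force_constant: float  # kcal mol^-1 Å^-2
    samples: np.ndarray  # R values, Å

    def __post_init__(self):
        if self.force_constant <= 0 and not np.isclose(self.force_constant, 0.0):
            raise ParameterError(
                f"force_constant must be >= 0, got {self.force_constant}"
            )
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise EmptyDataError(
                f"window at center {self.center} has no samples"
            )
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias_energy(self, r: np.ndarray, half_k: bool = False) -> np.ndarray:
        """w(R) on r; ``half_k`` switches to the ½k(R−c)² convention."""
        pref = 0.5 if half_k else 1.0
        return pref * self.force_constant * (np.asarray(r) - self.center) ** 2


# ---------------------------------------------------------------------------
# trajectory readers / writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def _read_xyz(path: Path) -> list[Frame]:
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"expected atom count, got {lines[i]!r}", i + 1) from exc
        if i + 1 + natoms >= n_lines + 1 and i + 1 + natoms > n_lines:
            raise FormatError(
                f"truncated XYZ frame starting at line {i + 1}: "
                f"{natoms} atoms declared, file ends early"
            )
        comment = lines[i + 1] if i + 1 < n_lines else ""
        time = None
        for tok in comment.split():
            if tok.startswith("time="):
                try:
                    time = float(tok[5:])
                except ValueError:
                    pass
        atoms = []
        for j in range(natoms):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"malformed XYZ atom line {lines[ln]!r}", ln + 1)
            name = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(f"non-numeric coordinate in {lines[ln]!r}", ln + 1) from exc
            element = "".join(c for c in name if c.isalpha())[:2].capitalize() or name
            # single-letter elements dominate here (C, N, S, H, O)
            if element[:1].upper() in "CNSHO" and element.upper() not in ("CL", "NA"):
                element = element[0].upper()
            atoms.append(AtomRecord(name=name, element=element, position=np.array(xyz)))
        frames.append(Frame(index=len(frames), atoms=tuple(atoms), time=time))
        i += 2 + natoms
    if not frames:
        raise EmptyDataError(f"no frames found in {path}")
    return frames


def _read_pdb(path: Path) -> list[Frame]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames: list[Frame] = []
    for k, model in enumerate(structure):
        atoms = []
        for atom in model.get_atoms():
            res = atom.get_parent()
            element = atom.element if atom.element else atom.get_name()[0]
            atoms.append(
                AtomRecord(
                    name=atom.get_name(),
                    element=element,
                    position=np.asarray(atom.get_coord(), dtype=float),
                    residue=res.get_resname().strip(),
                )
            )
        if atoms:
            frames.append(Frame(index=k, atoms=tuple(atoms)))
    if not frames:
        raise EmptyDataError(f"no MODEL records with atoms found in {path}")
    return frames


def read_frames(
    path: str | Path,
    format: str,
    role_map: RoleMap,
    temperature: float = 283.15,
) -> FrameSeries:
    """Read a multi-frame XYZ or MODEL-delimited PDB trajectory.

    Every required role must resolve to exactly one atom in every frame;
    otherwise a :class:`RoleResolutionError` naming the role and frame is
    raised.  Coordinates are in Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "xyz":
        frames = _read_xyz(path)
    elif fmt == "pdb":
        frames = _read_pdb(path)
    else:
        raise ParameterError(f"unknown trajectory format {format!r} (use 'xyz' or 'pdb')")
    # atom-count consistency check happens in FrameSeries, but PDB models
    # may legitimately differ in Biopython's eyes — surface it as a format error
    series = FrameSeries(frames=tuple(frames), role_map=role_map, temperature=temperature)
    series.validate_roles()
    return series


def write_frames(series: FrameSeries, path: str | Path) -> Path:
    """Write a FrameSeries as multi-frame XYZ at full text precision."""
    path = Path(path)
    out = []
    for frame in series.frames:
        out.append(str(len(frame.atoms)))
        comment = f"frame={frame.index}"
        if frame.time is not None:
            comment += f" time={_fmt(frame.time)}"
        out.append(comment)
        for a in frame.atoms:
            x, y, z = (_fmt(v) for v in a.position)
            out.append(f"{a.name} {x} {y} {z}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# umbrella-window series
# ---------------------------------------------------------------------------


def read_window_series(
    paths: Sequence[str | Path],
    metadata: Sequence[tuple[float, float]],
) -> list[UmbrellaWindow]:
    """Read one whitespace-delimited time-series file per window.

    The last column of each file is R in Å; ``metadata`` pairs are
    (bias center, force constant) in file order.  Windows are returned
    sorted by bias center.
    """
    if len(paths) != len(metadata):
        raise ParameterError(
            f"metadata count ({len(metadata)}) does not match file count ({len(paths)})"
        )
    windows = []
    for p, (center, k) in zip(paths, metadata):
        p = Path(p)
        samples = []
        for ln, line in enumerate(p.read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                samples.append(float(line.split()[-1]))
            except ValueError as exc:
                raise ParseError(f"non-numeric row in {p.name}: {line!r}", ln) from exc
        if not samples:
            raise EmptyDataError(f"window file {p} contains no samples")
        windows.append(
            UmbrellaWindow(center=center, force_constant=k, samples=np.array(samples))
        )
    windows.sort(key=lambda w: w.center)
    return windows


def write_window_series(
    windows: Iterable[UmbrellaWindow], outdir: str | Path, prefix: str = "window"
) -> list[Path]:
    """Write one two-column (step, R) text file per window; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, w in enumerate(windows):
        p = outdir / f"{prefix}_{i:02d}.dat"
        lines = [f"# center={_fmt(w.center)} k={_fmt(w.force_constant)}"]
        lines += [f"{j} {_fmt(r)}" for j, r in enumerate(w.samples)]
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# result writing + manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    profiles: Mapping[str, object],
    outdir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    warnings: Sequence[str] = (),
    extra_files: Sequence[Path] = (),
) -> dict:
    """Write CSV tables and profile grids plus a JSON run manifest.

    ``profiles`` values must expose ``to_frame() -> DataFrame`` (PMF
    profiles, free-energy surfaces) or already be DataFrames.  The
    manifest records the config, seed, warnings, and a SHA-256 checksum
    for every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for name, prof in profiles.items():
        df = prof.to_frame() if hasattr(prof, "to_frame") else prof
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    manifest = {
        "seed": seed,
        "config": dict(config) if config else {},
        "warnings": list(warnings),
        "files": [
            {"path": str(p.relative_to(outdir)) if p.is_relative_to(outdir) else str(p),
             "sha256": _sha256(p)}
            for p in sorted(list(written) + [Path(p) for p in extra_files])
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
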