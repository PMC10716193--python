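"""Molecular structures, fragment partitions and file I/O.

The central container is :class:`AtomicSystem`: coordinates (Bohr), element
symbols and per-atom scaling ratios ``eta`` (atom-in-molecule over free-atom
response, e.g. Hirshfeld-volume or Mulliken-population ratios).  Fragments
are named, disjoint sets of atom indices covering the whole system; for PDB
sources they are usually the residues.

Indexing convention: atoms are 0-based internally; every 3N-dimensional
object is ordered by the composite index ``mu = 3*A + i`` with ``i`` in
``{0, 1, 2}`` for the x, y, z Cartesian components of atom ``A``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "AtomicSystem",
    "FragmentPartition",
    "read_structure",
    "write_xyz",
    "load_eta",
    "partition_from_pdb",
]

#: Minimum allowed interatomic distance (Bohr) before input is rejected.
DEFAULT_CLASH_THRESHOLD = 0.5


@dataclass(frozen=True)
class AtomicSystem:
    """A molecular structure with per-atom QDO scaling ratios.

    Parameters
    ----------
    elements
        Chemical symbols, length N.
    positions
        (N, 3) array of Cartesian coordinates in Bohr.
    eta
        Optional (N,) array of positive atom-in-molecule ratios.
    residue_labels, chain_labels
        Optional per-atom labels populated from PDB records; residue labels
        are "<chain>:<resname><resseq>" strings.
    """

    elements: tuple[str, ...]
    positions: np.ndarray
    eta: np.ndarray | None = None
    residue_labels: tuple[str, ...] | None = None
    chain_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = np.ascontiguousarray(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {pos.shape}")
        if pos.shape[0] != len(self.elements):
            raise ValueError("elements and positions length mismatch")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        if self.eta is not None:
            eta = np.asarray(self.eta, dtype=float)
            if eta.shape != (pos.shape[0],):
                raise ValueError("eta must have one entry per atom")
            if np.any(eta <= 0):
                bad = int(np.argmax(eta <= 0))
                raise ValueError(f"eta must be positive; atom {bad} has eta={eta[bad]}")
            object.__setattr__(self, "eta", eta)
        self._check_clashes()

    def _check_clashes(self, threshold: float = DEFAULT_CLASH_THRESHOLD) -> None:
        if self.n_atoms < 2:
            return
        d = self.distance_matrix()
        np.fill_diagonal(d, np.inf)
        if d.min() < threshold:
            a, b = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"atoms {a} and {b} are {d[a, b]:.3f} Bohr apart "
                f"(< clash threshold {threshold} Bohr)"
            )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def distance_matrix(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def masses(self) -> np.ndarray:
        """Standard atomic masses (amu), used only for centers of mass."""
        return np.array([gemmi.Element(el).weight for el in self.elements])

    def with_eta(self, eta: np.ndarray) -> "AtomicSystem":
        return replace(self, eta=np.asarray(eta, dtype=float))


@dataclass(frozen=True)
class FragmentPartition:
    """Named, pairwise-disjoint atom-index sets covering a system exactly."""

    names: tuple[str, ...]
    fragments: tuple[frozenset[int], ...]
    n_atoms: int

    def __post_init__(self) -> None:
        if len(self.names) != len(self.fragments):
            raise ValueError("names/fragments length mismatch")
        if any(len(f) == 0 for f in self.fragments):
            raise ValueError("empty fragment")
        seen: dict[int, str] = {}
        for name, frag in zip(self.names, self.fragments):
            for a in frag:
                if a in seen:
                    raise ValueError(
                        f"atom {a} appears in fragments '{seen[a]}' and '{name}'"
                    )
                seen[a] = name
        missing = set(range(self.n_atoms)) - set(seen)
        if missing:
            raise ValueError(f"partition does not cover atoms {sorted(missing)}")
        extra = set(seen) - set(range(self.n_atoms))
        if extra:
            raise ValueError(f"partition references unknown atoms {sorted(extra)}")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def atom_indices(self, alpha: int) -> np.ndarray:
        """Sorted atom indices of fragment ``alpha``."""
        return np.array(sorted(self.fragments[alpha]), dtype=int)

    def composite_indices(self, alpha: int) -> np.ndarray:
        """Sorted composite (3N) indices of fragment ``alpha``."""
        atoms = self.atom_indices(alpha)
        return (3 * atoms[:, None] + np.arange(3)[None, :]).ravel()

    @classmethod
    def single(cls, n_atoms: int, name: str = "all") -> "FragmentPartition":
        return cls((name,), (frozenset(range(n_atoms)),), n_atoms)

    @classmethod
    def from_dict(cls, spec: dict[str, list[int]], n_atoms: int) -> "FragmentPartition":
        names = tuple(spec)
        frags = tuple(frozenset(int(a) for a in spec[n]) for n in names)
        return cls(names, frags, n_atoms)

    def to_json(self, path: str | Path) -> None:
        payload = {n: sorted(f) for n, f in zip(self.names, self.fragments)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, n_atoms: int) -> "FragmentPartition":
        return cls.from_dict(json.loads(Path(path).read_text()), n_atoms)


def _known_elements() -> frozenset[str]:
    from .parameters import FreeAtomReference

    return frozenset(FreeAtomReference.packaged().table.index)


def _read_xyz(path: Path) -> AtomicSystem:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed XYZ header") from exc
    elements: list[str] = []
    coords: list[list[float]] = []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path} line {ln}: expected 'El x y z'")
        elements.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    if len(elements) != n:
        raise ValueError(f"{path}: header declares {n} atoms, found {len(elements)}")
    pos = np.asarray(coords) * ANGSTROM_TO_BOHR
    return AtomicSystem(tuple(elements), pos)


def _read_pdb(path: Path) -> AtomicSystem:
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no MODEL found")
    model = st[0]  # first MODEL only
    elements: list[str] = []
    coords: list[list[float]] = []
    res_labels: list[str] = []
    chain_labels: list[str] = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                sym = atom.element.name
                elements.append(sym)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                res_labels.append(f"{chain.name}:{res.name}{res.seqid.num}")
                chain_labels.append(chain.name)
    if not elements:
        raise ValueError(f"{path}: no atoms parsed")
    if "H" not in elements:
        warnings.warn(f"{path}: no hydrogens present", stacklevel=2)
    pos = np.asarray(coords) * ANGSTROM_TO_BOHR
    return AtomicSystem(
        tuple(elements), pos, residue_labels=tuple(res_labels),
        chain_labels=tuple(chain_labels),
    )


def read_structure(path: str | Path, format: str | None = None) -> AtomicSystem:
    """Read a molecular structure from an XYZ or PDB file.

    XYZ coordinates are in Angstrom and are converted to Bohr.  For PDB
    files only the first MODEL is used and alternate locations other than
    'A' or blank are skipped.  Element symbols must be present in the
    packaged free-atom reference table.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if format not in ("pdb", "xyz"):
        raise ValueError(f"unknown format {format!r}")
    system = _read_pdb(path) if format == "pdb" else _read_xyz(path)
    known = _known_elements()
    for i, el in enumerate(system.elements):
        if el not in known:
            raise ValueError(
                f"{path} atom {i + 1}: unknown element {el!r} "
                f"(not in free-atom reference table)"
            )
    return system


def write_xyz(system: AtomicSystem, path: str | Path, comment: str = "") -> None:
    """Write a system to XYZ (Angstrom)."""
    lines = [str(system.n_atoms), comment.replace("\n", " ")]
    for el, xyz in zip(system.elements, system.positions * BOHR_TO_ANGSTROM):
        lines.append(f"{el:2s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_eta(path: str | Path, system: AtomicSystem) -> AtomicSystem:
    """Attach per-atom scaling ratios from a sidecar table.

    The table is whitespace- or comma-delimited with either one ``eta``
    value per line in atom order, or two columns ``atom_id eta`` keyed by
    1-based atom id (any order).  Lines starting with '#' are skipped.
    """
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip().replace(",", " ")
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() in ("atom_id", "id", "eta"):  # header row
            continue
        rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"{path}: no eta values found")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: inconsistent column count")
    if ncol == 1:
        eta = np.array([r[0] for r in rows])
    elif ncol == 2:
        eta = np.full(len(rows), np.nan)
        for aid, value in rows:
            idx = int(aid) - 1
            if not 0 <= idx < len(rows):
                raise ValueError(f"{path}: atom id {int(aid)} out of range")
            eta[idx] = value
        if np.any(np.isnan(eta)):
            raise ValueError(f"{path}: duplicate or missing atom ids")
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns, got {ncol}")
    if len(eta) != system.n_atoms:
        raise ValueError(
            f"{path}: {len(eta)} eta values for {system.n_atoms} atoms"
        )
    if np.any(eta <= 0):
        bad = int(np.argmax(eta <= 0)) + 1
        raise ValueError(f"{path}: non-positive eta for atom {bad}")
    return system.with_eta(eta)


def partition_from_pdb(
    system: AtomicSystem,
    scheme: str = "residue",
    spec: dict[str, list[int]] | None = None,
) -> FragmentPartition:
    """Build a fragment partition from PDB labels or an explicit spec.

    ``scheme='residue'`` groups atoms by (chain, residue); ``'chain'`` by
    chain; ``'explicit'`` takes ``spec`` mapping fragment names to 0-based
    atom-index lists (validated for disjoint exact cover).
    """
    if scheme == "explicit":
        if spec is None:
            raise ValueError("scheme='explicit' requires a spec")
        return FragmentPartition.from_dict(spec, system.n_atoms)
    labels = system.residue_labels if scheme == "residue" else system.chain_labels
    if scheme not in ("residue", "chain"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if labels is None:
        raise ValueError(f"scheme={scheme!r} requires PDB residue/chain labels")
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    # residues ordered by first occurrence, which follows (chain, resseq)
    # for standards-conforming PDB files
    return FragmentPartition.from_dict(groups, system.n_atoms)
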