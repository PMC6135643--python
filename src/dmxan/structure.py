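"""Snapshot ingestion, absorber-centred cluster extraction and RdF analysis.

Coordinates are Cartesian ångström throughout.  Snapshot sequences come from
multi-model PDB files (read and written through biotite) or plain multi-frame
XYZ files; role labels (FE, C_CO, O_CO, N_HIS, N_PYR1..4, ...) are attached
from atom names through a user-editable mapping table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AtomSite",
    "Snapshot",
    "Cluster",
    "RdFResult",
    "DEFAULT_LABEL_MAP",
    "ATOMIC_NUMBERS",
    "read_frames",
    "write_frames",
    "subsample",
    "select_cluster",
    "rdf",
]

ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "FE": 26, "Fe": 26,
}

# atom-name -> role-label mapping for the heme-site model written by the
# sampler; users may pass their own table to read_frames.
DEFAULT_LABEL_MAP = {
    "FE": "FE",
    "C": "C_CO",
    "O": "O_CO",
    "NE2": "N_HIS",
    "N1": "N_PYR1",
    "N2": "N_PYR2",
    "N3": "N_PYR3",
    "N4": "N_PYR4",
}


@dataclass
class AtomSite:
    """One atom: chemical symbol, atomic number, role label, position (Å)."""

    element: str
    Z: int
    label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")


@dataclass
class Snapshot:
    """One frame: an ordered list of sites with a frame ordinal and time (ps)."""

    sites: list[AtomSite]
    index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        n_fe = sum(1 for s in self.sites if s.label == "FE")
        if n_fe != 1:
            raise ValueError(f"snapshot must contain exactly one FE site, found {n_fe}")

    @property
    def absorber(self) -> AtomSite:
        return next(s for s in self.sites if s.label == "FE")

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r} in snapshot {self.index}")

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])


@dataclass
class Cluster:
    """Absorber plus its neighbours sorted by distance (non-decreasing)."""

    absorber: AtomSite
    neighbors: list[AtomSite]
    max_size: int

    def __post_init__(self) -> None:
        d = self.distances()
        if np.any(np.diff(d) < 0):
            raise ValueError("cluster neighbours must be sorted by distance")
        if len(self.neighbors) > self.max_size:
            raise ValueError("cluster larger than max_size")

    def distances(self) -> np.ndarray:
        a = self.absorber.position
        return np.array([np.linalg.norm(s.position - a) for s in self.neighbors])


@dataclass
class RdFResult:
    """Per-frame distance histogram and running coordination number.

    ``density`` is counts per frame per bin (histogram convention — no
    4*pi*r^2*rho normalisation, so peak positions read off as histogram
    modes); ``coordination`` is the mean number of selected atoms within r,
    evaluated at the upper edge of each bin.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    coordination: np.ndarray
    group: tuple[str, ...] = field(default_factory=tuple)
    n_frames: int = 0


# ---------------------------------------------------------------------------
# frame I/O

def _sites_from_names(names, elements, coords, label_map) -> list[AtomSite]:
    sites = []
    for name, elem, xyz in zip(names, elements, coords):
        label = label_map.get(name.strip(), name.strip())
        symbol = elem.strip() or name.strip()[:2]
        z = ATOMIC_NUMBERS.get(symbol, ATOMIC_NUMBERS.get(symbol.upper().capitalize(), 6))
        sites.append(AtomSite(symbol, z, label, np.asarray(xyz, dtype=float)))
    return sites


def _read_pdb(path, label_map, frame_dt: float) -> list[Snapshot]:
    from biotite.structure.io import pdb

    pdbfile = pdb.PDBFile.read(str(path))
    stack = pdbfile.get_structure()  # AtomArrayStack, model axis first
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    snapshots = []
    for i in range(coords.shape[0]):
        sites = _sites_from_names(stack.atom_name, stack.element, coords[i], label_map)
        snapshots.append(Snapshot(sites, index=i, time=i * frame_dt))
    return snapshots


def _read_xyz(path, label_map, frame_dt: float) -> list[Snapshot]:
    snapshots = []
    with open(path) as fh:
        lines = fh.readlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: malformed atom-count line {lines[i]!r}") from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ValueError(f"{path}:{i + 1}: frame truncated ({natoms} atoms declared)")
        comment = lines[i + 1].strip()
        time = frame * frame_dt
        if "time=" in comment:
            try:
                time = float(comment.split("time=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        scale = 10.0 if "units=nm" in comment else 1.0  # Å internally
        names, elements, coords = [], [], []
        for j in range(natoms):
            lineno = i + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno + 1}: expected 'name x y z', got {lines[lineno]!r}")
            try:
                xyz = [scale * float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno + 1}: non-numeric coordinate") from exc
            names.append(parts[0])
            elements.append(parts[0])
            coords.append(xyz)
        snapshots.append(Snapshot(_sites_from_names(names, elements, coords, label_map),
                                  index=frame, time=time))
        frame += 1
        i += 2 + natoms
    return snapshots


def read_frames(path, fmt: str | None = None, label_map=None, frame_dt: float = 1.0) -> list[Snapshot]:
    """Read a multi-model PDB or multi-frame XYZ trajectory into snapshots.

    ``fmt`` is 'pdb' or 'xyz'; inferred from the filename suffix when None.
    ``frame_dt`` assigns frame times (ps) when the file carries none.
    Frames with differing atom counts are rejected.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    if fmt is None:
        fmt = "pdb" if str(path).lower().endswith(".pdb") else "xyz"
    if fmt == "pdb":
        frames = _read_pdb(path, label_map, frame_dt)
    elif fmt == "xyz":
        frames = _read_xyz(path, label_map, frame_dt)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r} (expected 'pdb' or 'xyz')")
    counts = {len(f.sites) for f in frames}
    if len(counts) > 1:
        bad = [f.index for f in frames if len(f.sites) != len(frames[0].sites)]
        raise ValueError(f"frames differ in atom count; offending frame indices {bad}")
    return frames


_LABEL_TO_NAME = {v: k for k, v in DEFAULT_LABEL_MAP.items()}
_LABEL_TO_RES = {"FE": "HEM", "C_CO": "CO", "O_CO": "CO", "N_HIS": "HIS",
                 "N_PYR1": "HEM", "N_PYR2": "HEM", "N_PYR3": "HEM", "N_PYR4": "HEM"}


def write_frames(frames: list[Snapshot], path, fmt: str | None = None) -> None:
    """Write snapshots as a multi-model PDB (via biotite) or multi-frame XYZ."""
    if fmt is None:
        fmt = "pdb" if str(path).lower().endswith(".pdb") else "xyz"
    if fmt == "xyz":
        with open(path, "w") as fh:
            for f in frames:
                fh.write(f"{len(f.sites)}\n")
                fh.write(f"frame={f.index} time={f.time}\n")
                for s in f.sites:
                    x, y, z = s.position
                    fh.write(f"{s.element:<3s} {x:14.8f} {y:14.8f} {z:14.8f}\n")
        return
    if fmt != "pdb":
        raise ValueError(f"unknown trajectory format {fmt!r}")

    import biotite.structure as struc
    from biotite.structure.io import pdb

    n = len(frames[0].sites)
    arr = struc.AtomArray(n)
    for i, s in enumerate(frames[0].sites):
        arr.atom_name[i] = _LABEL_TO_NAME.get(s.label, s.label[:4])
        arr.element[i] = s.element.upper()
        arr.res_name[i] = _LABEL_TO_RES.get(s.label, "UNK")
        arr.res_id[i] = 1
        arr.chain_id[i] = "A"
        arr.hetero[i] = True
    coords = np.array([[s.position for s in f.sites] for f in frames])
    stack = struc.from_template(arr, coords)
    pdbfile = pdb.PDBFile()
    pdbfile.set_structure(stack)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------------
# selection and analysis

def subsample(frames: list[Snapshot], every: float, tol: float = 1e-6) -> list[Snapshot]:
    """Keep frames whose time is an integer multiple of ``every`` ps."""
    if every <= 0:
        raise ValueError(f"subsample interval must be positive, got {every}")
    out = []
    for f in frames:
        ratio = f.time / every
        if abs(ratio - round(ratio)) * every <= tol:
            out.append(f)
    return out


_SHORTFALL_SEEN: set[tuple[int, int]] = set()


def select_cluster(snapshot: Snapshot, k: int = 100) -> Cluster:
    """The k nearest non-absorber sites around the Fe absorber.

    Distances are Euclidean; ties are broken by input order (stable sort).
    If the snapshot holds fewer than k non-absorber atoms, all of them are
    returned and a warning is logged.
    """
    absorber = snapshot.absorber
    others = [s for s in snapshot.sites if s is not absorber]
    dists = [float(np.linalg.norm(s.position - absorber.position)) for s in others]
    order = np.argsort(dists, kind="stable")
    if len(others) < k and (len(others), k) not in _SHORTFALL_SEEN:
        _SHORTFALL_SEEN.add((len(others), k))
        log.warning("snapshot %d has only %d non-absorber atoms (< k=%d); using all "
                    "(further identical shortfalls not repeated)",
                    snapshot.index, len(others), k)
    keep = order[:k]
    return Cluster(absorber, [others[i] for i in keep], max_size=k)


def rdf(
    frames: list[Snapshot],
    group: set[str] | list[str],
    bin_width: float = 0.02,
    r_max: float = 10.0,
) -> RdFResult:
    """Absorber–group distance histogram plus running coordination number.

    ``density[b]`` is the mean number of selected atoms per frame falling in
    bin b; ``coordination[b]`` is the mean number of selected atoms within
    the upper edge of bin b (hence non-decreasing, with terminal value the
    mean selected-group size when r_max exceeds all distances).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    group = set(group)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    n_sel = 0
    for f in frames:
        a = f.absorber.position
        sel = [s for s in f.sites if s.label in group and s is not f.absorber]
        n_sel += len(sel)
        if sel:
            d = np.linalg.norm(np.array([s.position for s in sel]) - a, axis=1)
            h, _ = np.histogram(d, bins=edges)
            counts += h
    if n_sel == 0:
        raise ValueError(f"no atoms match group selection {sorted(group)!r}")
    density = counts / len(frames)
    coordination = np.cumsum(density)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdFResult(centers, density, coordination, tuple(sorted(group)), len(frames))
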