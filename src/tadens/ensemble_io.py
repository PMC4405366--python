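"""Structural ensembles as multi-model PDB files.

An :class:`Ensemble` is the universal input of every analysis stage: a
topology (residue sequence plus atom list) and a ``(frames, atoms, 3)``
coordinate array in Angstrom with normalised per-frame weights.  This module
reads and writes MODEL/ENDMDL multi-model PDB files (via biotite for the
record format), selects atoms and frames, and provides the 61-residue
wild-type p53 transactivation-domain sequence together with point-mutation
editing for the cancer-associated variants.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Topology", "Ensemble", "AtomSelection",
    "read_multimodel_pdb", "write_multimodel_pdb", "subset_frames",
    "p53_tad_fixture", "apply_point_mutations",
    "P53_TAD_SEQUENCE", "HELIX_WINDOWS",
]

#: Wild-type p53 transactivation domain, residues 1-61.
P53_TAD_SEQUENCE = "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGPD"

#: The three partial-helix segments of p53-TAD (author numbering, inclusive).
HELIX_WINDOWS = ((18, 27), (40, 44), (48, 52))

_BACKBONE_NAMES = ("N", "CA", "C")
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"


def _one_to_three(letter: str) -> str:
    return ProteinSequence.convert_letter_1to3(letter)


@dataclass(frozen=True)
class Topology:
    """Residue sequence and atom list of a single chain.

    ``residues`` is an ordered tuple of ``(residue_number, residue_name)``
    with strictly increasing numbers; ``atoms`` is an ordered tuple of
    ``(atom_name, residue_index, element)`` where ``residue_index`` indexes
    into ``residues`` (0-based).
    """
    chain_id: str
    residues: tuple[tuple[int, str], ...]
    atoms: tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        nums = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        for name, idx, _elem in self.atoms:
            if not 0 <= idx < len(self.residues):
                raise ValueError(
                    f"atom {name!r} references residue index {idx} "
                    f"out of range")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([n for n, _ in self.residues], dtype=int)

    @property
    def sequence(self) -> str:
        """One-letter sequence derived from the residue names."""
        return "".join(_three_to_one(name) for _, name in self.residues)

    def residue_name(self, number: int) -> str:
        for num, name in self.residues:
            if num == number:
                return name
        raise KeyError(f"no residue numbered {number}")

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        """Index into the atom list for (residue number, atom name)."""
        numbers = self.residue_numbers
        for i, (name, ridx, _el) in enumerate(self.atoms):
            if name == atom_name and numbers[ridx] == residue_number:
                return i
        raise KeyError(f"no atom {atom_name} in residue {residue_number}")

    @classmethod
    def from_sequence(cls, sequence: str, start: int = 1,
                      chain_id: str = "A",
                      atom_names: Sequence[str] = ("CA",)) -> "Topology":
        """Build a topology from a one-letter sequence with the given
        per-residue atoms (default: a plain C-alpha trace)."""
        residues = tuple((start + i, _one_to_three(aa))
                         for i, aa in enumerate(sequence))
        atoms = tuple((name, i, _BACKBONE_ELEMENTS.get(name, name[0]))
                      for i in range(len(sequence)) for name in atom_names)
        return cls(chain_id=chain_id, residues=residues, atoms=atoms)


@dataclass(frozen=True)
class AtomSelection:
    """Atom subset specification: a mode plus an inclusive residue range."""
    mode: str = "all"  # one of: CA-only, backbone, heavy-atoms, all
    residue_range: tuple[int, int] | str = "all"

    _MODES = ("CA-only", "backbone", "heavy-atoms", "all")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unknown selection mode {self.mode!r}; "
                             f"expected one of {self._MODES}")

    def indices(self, topology: Topology) -> np.ndarray:
        """Atom indices of the selection applied to ``topology``."""
        numbers = topology.residue_numbers
        keep = []
        for i, (name, ridx, element) in enumerate(topology.atoms):
            if self.residue_range != "all":
                lo, hi = self.residue_range
                if not lo <= numbers[ridx] <= hi:
                    continue
            if self.mode == "CA-only" and name != "CA":
                continue
            if self.mode == "backbone" and name not in _BACKBONE_NAMES:
                continue
            if self.mode == "heavy-atoms" and element == "H":
                continue
            keep.append(i)
        if not keep:
            raise ValueError("selection is empty for this topology")
        return np.asarray(keep, dtype=int)


@dataclass(frozen=True)
class Ensemble:
    """A conformational ensemble: topology + (frames, atoms, 3) coordinates
    in Angstrom, with nonnegative frame weights summing to one."""
    topology: Topology
    coordinates: np.ndarray
    frame_weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom axis ({coords.shape[1]}) does not match "
                f"topology ({self.topology.n_atoms} atoms)")
        if coords.shape[0] == 0:
            raise ValueError("ensemble must contain at least one frame")
        if np.isnan(coords).any():
            raise ValueError("coordinates contain NaN")
        object.__setattr__(self, "coordinates", coords)
        w = self.frame_weights
        if w is None:
            w = np.full(coords.shape[0], 1.0 / coords.shape[0])
        else:
            w = np.asarray(w, dtype=float)
            if w.shape != (coords.shape[0],):
                raise ValueError("frame_weights length must equal n_frames")
            if (w < 0).any():
                raise ValueError("frame_weights must be nonnegative")
            total = w.sum()
            if total <= 0:
                raise ValueError("frame_weights must not sum to zero")
            if abs(total - 1.0) > 1e-9:
                w = w / total
        object.__setattr__(self, "frame_weights", w)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def ca_coordinates(self) -> np.ndarray:
        """(frames, residues, 3) coordinates of the C-alpha atoms, ordered
        by residue."""
        sel = AtomSelection("CA-only").indices(self.topology)
        if len(sel) != self.topology.n_residues:
            raise ValueError("not every residue has a CA atom")
        return self.coordinates[:, sel, :]

    def with_label(self, label: str) -> "Ensemble":
        return replace(self, label=label)


def _parse_model(pdb_file: PDBFile, model: int) -> struc.AtomArray:
    arr = pdb_file.get_structure(model=model, altloc="first")
    if (arr.ins_code != "").any():
        bad = arr.res_id[arr.ins_code != ""][0]
        raise ValueError(
            f"insertion codes are not supported (residue {bad}); "
            "simulated ensembles should not carry them")
    return arr


def read_multimodel_pdb(path, selection: AtomSelection | None = None
                        ) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One frame per MODEL record (a single unlabeled structure yields one
    frame).  Atom identity and order must be identical across models; the
    first mismatching MODEL is named in the error.  Residue numbering is
    taken verbatim from the file.
    """
    path = Path(path)
    pdb_file = PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models < 1:
        raise ValueError(f"{path}: no structure found")
    first = _parse_model(pdb_file, 1)
    ref_ids = list(zip(first.res_id.tolist(), first.atom_name.tolist()))
    frames = [first.coord]
    for m in range(2, n_models + 1):
        arr = _parse_model(pdb_file, m)
        ids = list(zip(arr.res_id.tolist(), arr.atom_name.tolist()))
        if ids != ref_ids:
            raise ValueError(
                f"{path}: MODEL {m} has inconsistent atoms "
                f"({len(ids)} vs {len(ref_ids)} in MODEL 1)")
        frames.append(arr.coord)
    coords = np.stack(frames).astype(float)

    res_starts = struc.get_residue_starts(first)
    res_index_of_atom = np.searchsorted(res_starts, np.arange(first.array_length()),
                                        side="right") - 1
    residues = tuple((int(first.res_id[s]), str(first.res_name[s]))
                     for s in res_starts)
    elements = [str(e) if e else str(n)[0]
                for e, n in zip(first.element, first.atom_name)]
    atoms = tuple((str(n), int(r), el) for n, r, el
                  in zip(first.atom_name, res_index_of_atom, elements))
    chain = str(first.chain_id[0]) if first.array_length() else "A"
    topo = Topology(chain_id=chain, residues=residues, atoms=atoms)

    if selection is not None:
        idx = selection.indices(topo)
        if selection.mode == "CA-only":
            wanted = topo.residue_numbers
            if selection.residue_range != "all":
                lo, hi = selection.residue_range
                wanted = wanted[(wanted >= lo) & (wanted <= hi)]
            have = {topo.residue_numbers[topo.atoms[i][1]] for i in idx}
            missing = [int(r) for r in wanted if int(r) not in have]
            if missing:
                raise ValueError(
                    f"{path}: residue {missing[0]} has no CA atom under "
                    "CA-only selection")
        kept_res = sorted({topo.atoms[i][1] for i in idx})
        res_remap = {old: new for new, old in enumerate(kept_res)}
        topo = Topology(
            chain_id=topo.chain_id,
            residues=tuple(topo.residues[i] for i in kept_res),
            atoms=tuple((topo.atoms[i][0], res_remap[topo.atoms[i][1]],
                         topo.atoms[i][2]) for i in idx))
        coords = coords[:, idx, :]
    return Ensemble(topology=topo, coordinates=coords, label=path.stem)


def _to_atom_array(ensemble: Ensemble, frame: int) -> struc.AtomArray:
    topo = ensemble.topology
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = ensemble.coordinates[frame]
    numbers = topo.residue_numbers
    arr.chain_id = np.full(n, topo.chain_id or "A")
    arr.res_id = np.array([numbers[r] for _, r, _ in topo.atoms])
    arr.res_name = np.array([topo.residues[r][1] for _, r, _ in topo.atoms])
    arr.atom_name = np.array([name for name, _, _ in topo.atoms])
    arr.element = np.array([el for _, _, el in topo.atoms])
    return arr


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write the ensemble as a standards-conformant multi-model PDB file,
    one MODEL/ENDMDL pair per frame (also for single-frame ensembles)."""
    path = Path(path)
    stack = struc.stack([_to_atom_array(ensemble, f)
                         for f in range(ensemble.n_frames)])
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    buf = _io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if ensemble.n_frames == 1 and "MODEL" not in text:
        body = text.rstrip("\n")
        text = f"MODEL        1\n{body}\nENDMDL\n"
    try:
        path.write_text(text)
    except OSError as exc:
        raise OSError(f"cannot write ensemble to {path}: {exc}") from exc


def subset_frames(ensemble: Ensemble, stride: int = 1,
                  first: int = 0, last: int | None = None) -> Ensemble:
    """Frames ``first..last`` (inclusive, 0-based) taken every ``stride``;
    weights are renormalised.  Mirrors trajectory under-sampling such as
    keeping snapshots every 20 ps of the final segment of a run."""
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if last is None:
        last = ensemble.n_frames - 1
    if not 0 <= first <= last < ensemble.n_frames:
        raise ValueError(
            f"invalid frame range [{first}, {last}] for "
            f"{ensemble.n_frames} frames")
    idx = np.arange(first, last + 1, stride)
    if idx.size == 0:
        raise ValueError("frame subset is empty")
    return Ensemble(topology=ensemble.topology,
                    coordinates=ensemble.coordinates[idx],
                    frame_weights=ensemble.frame_weights[idx],
                    label=ensemble.label)


def p53_tad_fixture(atom_names: Sequence[str] = ("CA",)) -> Topology:
    """Topology of the wild-type p53 transactivation domain, residues 1-61
    (C-alpha trace by default)."""
    return Topology.from_sequence(P53_TAD_SEQUENCE, start=1,
                                  atom_names=atom_names)


def _parse_mutation(mut) -> tuple[str | None, int, str]:
    if isinstance(mut, str):
        orig, pos, new = mut[0], int(mut[1:-1]), mut[-1]
        return orig.upper(), pos, new.upper()
    pos, new = mut
    return None, int(pos), str(new).upper()


def apply_point_mutations(topology: Topology, mutations: Iterable) -> Topology:
    """Relabel residues according to point mutations, applied atomically.

    Mutations are either ``"K24N"`` strings (the wild-type letter is
    verified) or ``(position, new_letter)`` tuples.  Sequence-level
    relabeling only; atoms and coordinates are untouched.
    """
    numbers = topology.residue_numbers.tolist()
    residues = list(topology.residues)
    edits = []
    for mut in mutations:
        orig, pos, new = _parse_mutation(mut)
        if pos not in numbers:
            raise ValueError(f"mutation position {pos} not in topology")
        i = numbers.index(pos)
        if orig is not None:
            actual = _three_to_one(residues[i][1])
            if actual != orig:
                raise ValueError(
                    f"mutation expects {orig} at position {pos}, "
                    f"but topology has {actual}")
        edits.append((i, pos, new))
    for i, pos, new in edits:
        residues[i] = (pos, _one_to_three(new))
    return Topology(chain_id=topology.chain_id, residues=tuple(residues),
                    atoms=topology.atoms)
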