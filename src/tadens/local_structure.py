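"""Per-residue helicity and helical-substate analysis.

Helix assignment uses a dihedral criterion plus a minimum-run rule: a
residue is helical iff its backbone (phi/psi) or C-alpha virtual torsion
falls in the alpha window *and* it belongs to a run of at least three such
residues.  Profiles are weighted column means of the binary state matrix;
the uncertainty convention is the absolute difference between two
independent runs (the folding/control pattern used to assess convergence
of simulated ensembles).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._geometry import dihedral
from .ensemble_io import Ensemble
from .synthetic_ensembles import enforce_min_run, MIN_HELICAL_RUN

__all__ = [
    "HelicityProfile", "SubstateHistogram",
    "assign_helix", "helicity_profile", "region_mean_helicity",
    "substate_histogram", "profile_rmsd", "merge_runs",
    "PHI_WINDOW", "PSI_WINDOW", "CA_TORSION_WINDOW",
]

# alpha-basin windows of the two assignment backends
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-67.0, -7.0)
CA_TORSION_WINDOW = (30.0, 70.0)


@dataclass(frozen=True)
class HelicityProfile:
    """Per-residue helical fraction with run-to-run uncertainty."""
    residue_numbers: np.ndarray
    fraction: np.ndarray
    uncertainty: np.ndarray
    n_frames: int
    assignment_backend: str = "ca-torsion"

    def __post_init__(self):
        f = np.asarray(self.fraction, float)
        u = np.asarray(self.uncertainty, float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("helical fractions must lie in [0, 1]")
        if (u < 0).any():
            raise ValueError("uncertainties must be nonnegative")
        object.__setattr__(self, "residue_numbers",
                           np.asarray(self.residue_numbers, int))
        object.__setattr__(self, "fraction", f)
        object.__setattr__(self, "uncertainty", u)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_numbers,
                             "helicity": self.fraction,
                             "uncertainty": self.uncertainty})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SubstateHistogram:
    """Weighted per-frame frequency of maximal helical runs, keyed by
    (start residue, end residue).  The cell sum equals the mean number of
    helical segments per frame and may exceed one."""
    cells: dict
    min_segment_length: int = MIN_HELICAL_RUN

    def __post_init__(self):
        for (a, b), v in self.cells.items():
            if b - a + 1 < self.min_segment_length:
                raise ValueError(f"segment ({a}, {b}) shorter than minimum")
            if v < 0:
                raise ValueError("cell frequencies must be nonnegative")

    @property
    def mean_segments_per_frame(self) -> float:
        return float(sum(self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, v) for (a, b), v in sorted(self.cells.items())]
        return pd.DataFrame(rows, columns=["start", "end", "frequency"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_matrix(self, residue_numbers: np.ndarray
                  ) -> pd.DataFrame:
        """Dense (start x end) matrix with residue-number axes."""
        nums = np.asarray(residue_numbers, int)
        mat = pd.DataFrame(0.0, index=nums, columns=nums)
        for (a, b), v in self.cells.items():
            mat.loc[a, b] = v
        return mat


def _virtual_torsion_states(ca: np.ndarray, window=CA_TORSION_WINDOW
                            ) -> np.ndarray:
    """Flag residues from C-alpha virtual torsions: the i..i+3 torsion in
    the window marks residues i+1 and i+2."""
    n_res = ca.shape[1]
    flags = np.zeros(ca.shape[:2], bool)
    if n_res >= 4:
        tor = dihedral(ca[:, :-3], ca[:, 1:-2], ca[:, 2:-1], ca[:, 3:])
        inside = (tor > window[0]) & (tor < window[1])
        flags[:, 1:n_res - 2] |= inside
        flags[:, 2:n_res - 1] |= inside
    return flags


def _phi_psi_states(ensemble: Ensemble) -> np.ndarray:
    topo = ensemble.topology
    n_res = topo.n_residues
    try:
        idx = np.array(
            [[topo.atom_index(int(num), name) for name in ("N", "CA", "C")]
             for num in topo.residue_numbers])
    except KeyError as exc:
        raise ValueError(
            f"phi-psi backend requires N, CA, C atoms: {exc}") from exc
    x = ensemble.coordinates
    n_xyz = x[:, idx[:, 0]]
    ca_xyz = x[:, idx[:, 1]]
    c_xyz = x[:, idx[:, 2]]
    flags = np.zeros((x.shape[0], n_res), bool)
    if n_res >= 2:
        phi = dihedral(c_xyz[:, :-1], n_xyz[:, 1:], ca_xyz[:, 1:],
                       c_xyz[:, 1:])
        psi = dihedral(n_xyz[:, :-1], ca_xyz[:, :-1], c_xyz[:, :-1],
                       n_xyz[:, 1:])
        phi_ok = (phi > PHI_WINDOW[0]) & (phi < PHI_WINDOW[1])
        psi_ok = (psi > PSI_WINDOW[0]) & (psi < PSI_WINDOW[1])
        # residue r (1..n-2) needs both its phi and its psi in the window;
        # terminal residues lack one dihedral and stay coil
        flags[:, 1:] = phi_ok
        flags[:, :-1] &= psi_ok
        flags[:, 0] = False
        flags[:, -1] = False
    return flags


def assign_helix(ensemble: Ensemble, backend: str = "ca-torsion"
                 ) -> np.ndarray:
    """Binary helical-state matrix (frames x residues).

    ``ca-torsion``: C-alpha virtual torsion i..i+3 in (30, 70) degrees
    flags residues i+1 and i+2.  ``phi-psi``: phi in (-100, -30) and psi in
    (-67, -7) degrees.  Both backends then relabel runs shorter than three
    residues as coil; chain-terminal residues without a defined dihedral
    are coil.
    """
    if backend == "ca-torsion":
        ca = ensemble.ca_coordinates()
        if ca.shape[1] < 4:
            raise ValueError("ca-torsion backend needs >= 4 consecutive "
                             "residues with CA atoms")
        flags = _virtual_torsion_states(ca)
    elif backend == "phi-psi":
        flags = _phi_psi_states(ensemble)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return enforce_min_run(flags)


def helicity_profile(states: np.ndarray,
                     weights: np.ndarray | None = None,
                     residue_numbers: np.ndarray | None = None,
                     backend: str = "ca-torsion") -> HelicityProfile:
    """Weighted column mean of the binary state matrix."""
    s = np.asarray(states, float)
    n_frames = s.shape[0]
    if weights is None:
        frac = s.mean(axis=0)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
        frac = w @ s
    if residue_numbers is None:
        residue_numbers = np.arange(1, s.shape[1] + 1)
    return HelicityProfile(residue_numbers=residue_numbers, fraction=frac,
                           uncertainty=np.zeros_like(frac),
                           n_frames=n_frames, assignment_backend=backend)


def ensemble_helicity(ensemble: Ensemble, backend: str = "ca-torsion"
                      ) -> HelicityProfile:
    """Convenience: assignment plus profile in one call."""
    states = assign_helix(ensemble, backend)
    return helicity_profile(states, ensemble.frame_weights,
                            ensemble.topology.residue_numbers, backend)


def merge_runs(a: HelicityProfile, b: HelicityProfile) -> HelicityProfile:
    """Combine two independent runs: mean fraction, uncertainty = |a - b|
    per residue (the folding/control convention)."""
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise ValueError("profiles cover different residues")
    return HelicityProfile(
        residue_numbers=a.residue_numbers,
        fraction=0.5 * (a.fraction + b.fraction),
        uncertainty=np.abs(a.fraction - b.fraction),
        n_frames=a.n_frames + b.n_frames,
        assignment_backend=a.assignment_backend)


def region_mean_helicity(profile: HelicityProfile, first: int, last: int
                         ) -> float:
    """Unweighted mean helical fraction over the inclusive residue range."""
    mask = ((profile.residue_numbers >= first)
            & (profile.residue_numbers <= last))
    if not mask.any():
        raise ValueError(f"no residues in range {first}-{last}")
    return float(profile.fraction[mask].mean())


def substate_histogram(states: np.ndarray,
                       weights: np.ndarray | None = None,
                       residue_numbers: np.ndarray | None = None
                       ) -> SubstateHistogram:
    """Each maximal helical run of length >= 3 in a frame adds that frame's
    weight to the (run start residue, run end residue) cell."""
    s = np.asarray(states, bool)
    n_frames, n_res = s.shape
    if weights is None:
        weights = np.full(n_frames, 1.0 / n_frames)
    else:
        weights = np.asarray(weights, float)
        weights = weights / weights.sum()
    if residue_numbers is None:
        residue_numbers = np.arange(1, n_res + 1)
    numbers = np.asarray(residue_numbers, int)
    padded = np.zeros((n_frames, n_res + 2), bool)
    padded[:, 1:-1] = s
    starts = np.argwhere(padded[:, 1:-1] & ~padded[:, :-2])
    ends_mask = padded[:, 1:-1] & ~padded[:, 2:]
    cells: dict = {}
    # walk runs frame by frame using the precomputed start positions
    end_positions = [np.flatnonzero(row) for row in ends_mask]
    per_frame_starts: dict = {}
    for f, col in starts:
        per_frame_starts.setdefault(f, []).append(col)
    for f, start_cols in per_frame_starts.items():
        ends = end_positions[f]
        for a in start_cols:
            b = ends[np.searchsorted(ends, a)]
            if b - a + 1 >= MIN_HELICAL_RUN:
                key = (int(numbers[a]), int(numbers[b]))
                cells[key] = cells.get(key, 0.0) + float(weights[f])
    return SubstateHistogram(cells=cells)


def profile_rmsd(a: HelicityProfile, b: HelicityProfile) -> float:
    """Root mean square difference of two profiles over identical ranges."""
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise ValueError("profiles cover different residue ranges")
    return float(np.sqrt(np.mean((a.fraction - b.fraction) ** 2)))
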