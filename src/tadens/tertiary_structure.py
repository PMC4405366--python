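"""Long-range structure: contact maps, distance distributions, compaction.

Contact probabilities follow the boundary-inclusive criterion (a pair is in
contact when its distance is *no greater than* the cutoff): 4.2 A on the
minimal heavy-atom distance for atomistic ensembles, 8.0 A on C-alpha
distances for C-alpha traces.  Pairs closer than ``min_sequence_separation``
along the chain are masked so that the maps report genuinely long-range
structure.  Convergence metrics (Pearson correlation and RMSD between two
maps) are computed over the unmasked upper triangle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .ensemble_io import AtomSelection, Ensemble

__all__ = [
    "ContactMap", "DistanceDistribution",
    "contact_map", "map_correlation", "map_rmsd",
    "distance_distribution", "radius_of_gyration",
    "HEAVY_ATOM_CUTOFF", "CA_CUTOFF", "MIN_SEQUENCE_SEPARATION",
]

HEAVY_ATOM_CUTOFF = 4.2        # Angstrom, minimal heavy-atom criterion
CA_CUTOFF = 8.0                # Angstrom, C-alpha trace convention
MIN_SEQUENCE_SEPARATION = 4    # |i - j| >= 4 counts as long-range


@dataclass(frozen=True)
class ContactMap:
    """Symmetric residue-pair contact-probability matrix.

    Masked entries (|i-j| below the separation threshold) are NaN."""
    residue_numbers: np.ndarray
    matrix: np.ndarray
    cutoff: float
    distance_mode: str
    min_sequence_separation: int

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        valid = ~np.isnan(m)
        if not np.allclose(m[valid & valid.T], m.T[valid & valid.T]):
            raise ValueError("matrix must be symmetric")
        vals = m[valid]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("contact probabilities must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "residue_numbers",
                           np.asarray(self.residue_numbers, int))

    def upper_triangle(self) -> np.ndarray:
        """Unmasked upper-triangle probabilities, row-major order."""
        iu = np.triu_indices(self.matrix.shape[0], 1)
        vals = self.matrix[iu]
        return vals[~np.isnan(vals)]

    def to_dense_tsv(self, path) -> None:
        nums = self.residue_numbers
        pd.DataFrame(self.matrix, index=nums, columns=nums).to_csv(
            path, sep="\t", na_rep="nan")

    def to_triplet_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(self.matrix.shape[0], 1)
        vals = self.matrix[iu]
        keep = ~np.isnan(vals)
        return pd.DataFrame({
            "residue_i": self.residue_numbers[iu[0][keep]],
            "residue_j": self.residue_numbers[iu[1][keep]],
            "probability": vals[keep]})


@dataclass(frozen=True)
class DistanceDistribution:
    """Weighted histogram of one inter-residue distance."""
    pair: tuple
    bin_edges: np.ndarray
    frequencies: np.ndarray
    mean: float
    std: float

    def __post_init__(self):
        e = np.asarray(self.bin_edges, float)
        f = np.asarray(self.frequencies, float)
        if (np.diff(e) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "frequencies", f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "frequency": self.frequencies})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def overlap(self, other: "DistanceDistribution") -> float:
        """Histogram overlap sum(min(p, q)) over shared bin edges."""
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("distributions use different bins")
        return float(np.minimum(self.frequencies, other.frequencies).sum())


def _per_residue_atom_groups(ensemble: Ensemble, heavy: bool) -> list:
    topo = ensemble.topology
    groups: list[list[int]] = [[] for _ in range(topo.n_residues)]
    for i, (name, ridx, element) in enumerate(topo.atoms):
        if heavy and element == "H":
            continue
        groups[ridx].append(i)
    return [np.asarray(g, int) for g in groups]


def contact_map(ensemble: Ensemble, cutoff: float | None = None,
                mode: str = "CA",
                min_sep: int = MIN_SEQUENCE_SEPARATION) -> ContactMap:
    """Fraction of frames (weighted) in which each residue pair is in
    contact.  ``mode='min-heavy-atom'`` uses the minimum distance over all
    heavy-atom pairs (default cutoff 4.2 A); ``mode='CA'`` uses the
    C-alpha distance (default cutoff 8.0 A).  The cutoff is inclusive."""
    if mode not in ("CA", "min-heavy-atom"):
        raise ValueError(f"unknown distance mode {mode!r}")
    if cutoff is None:
        cutoff = HEAVY_ATOM_CUTOFF if mode == "min-heavy-atom" else CA_CUTOFF
    numbers = ensemble.topology.residue_numbers
    n_res = numbers.size
    w = ensemble.frame_weights
    if mode == "CA":
        ca = ensemble.ca_coordinates()
        d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
        prob = np.einsum("f,fij->ij", w, (d <= cutoff).astype(float))
    else:
        groups = _per_residue_atom_groups(ensemble, heavy=True)
        if any(g.size == 0 for g in groups):
            empty = numbers[[k for k, g in enumerate(groups)
                             if g.size == 0][0]]
            raise ValueError(
                f"residue {empty} has no heavy atoms for min-heavy-atom "
                "mode")
        x = ensemble.coordinates
        prob = np.zeros((n_res, n_res))
        for i in range(n_res):
            gi = groups[i]
            for j in range(i + 1, n_res):
                gj = groups[j]
                diff = x[:, gi, None, :] - x[:, None, gj, :]
                dmin = np.sqrt(
                    np.sum(diff * diff, axis=-1).min(axis=(1, 2)))
                p = float(w @ (dmin <= cutoff))
                prob[i, j] = prob[j, i] = p
    ii, jj = np.meshgrid(np.arange(n_res), np.arange(n_res), indexing="ij")
    prob = np.where(np.abs(ii - jj) < min_sep, np.nan, prob)
    return ContactMap(residue_numbers=numbers, matrix=prob, cutoff=cutoff,
                      distance_mode=mode, min_sequence_separation=min_sep)


def _check_compatible(a: ContactMap, b: ContactMap) -> None:
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("contact maps have different shapes")
    if (a.distance_mode != b.distance_mode or a.cutoff != b.cutoff
            or a.min_sequence_separation != b.min_sequence_separation):
        raise ValueError("contact maps were computed with different "
                         "criteria and cannot be compared")


def map_correlation(a: ContactMap, b: ContactMap) -> float:
    """Pearson correlation over unmasked upper-triangle entries."""
    _check_compatible(a, b)
    x, y = a.upper_triangle(), b.upper_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a map has zero variance")
    return float(pearsonr(x, y).statistic)


def map_rmsd(a: ContactMap, b: ContactMap) -> float:
    """Root mean square entrywise difference over the unmasked upper
    triangle."""
    _check_compatible(a, b)
    x, y = a.upper_triangle(), b.upper_triangle()
    return float(np.sqrt(np.mean((x - y) ** 2)))


def distance_distribution(ensemble: Ensemble, i, j=None,
                          bin_width: float = 1.0) -> DistanceDistribution:
    """Weighted histogram (plus mean and SD) of the CA-CA distance between
    residues ``i`` and ``j``; ``i='end-to-end'`` uses the chain termini."""
    numbers = ensemble.topology.residue_numbers
    if i == "end-to-end":
        i, j = int(numbers[0]), int(numbers[-1])
    if i == j:
        raise ValueError("distance of a residue to itself is not defined")
    ca = ensemble.ca_coordinates()
    index = {int(n): k for k, n in enumerate(numbers)}
    d = np.linalg.norm(ca[:, index[int(i)]] - ca[:, index[int(j)]], axis=-1)
    w = ensemble.frame_weights
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    freq, edges = np.histogram(d, bins=edges, weights=w)
    mean = float(w @ d)
    var = float(w @ (d - mean) ** 2)
    return DistanceDistribution(pair=(int(i), int(j)), bin_edges=edges,
                                frequencies=freq, mean=mean,
                                std=float(np.sqrt(var)))


def radius_of_gyration(ensemble: Ensemble,
                       selection: AtomSelection | None = None
                       ) -> tuple[np.ndarray, float]:
    """Mass-uniform radius of gyration per frame and its weighted mean."""
    if selection is None:
        x = ensemble.coordinates
    else:
        x = ensemble.coordinates[:, selection.indices(ensemble.topology), :]
    centroid = x.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((x - centroid) ** 2, axis=-1), axis=-1))
    return rg, float(ensemble.frame_weights @ rg)
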