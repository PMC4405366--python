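"""Wild-type vs mutant comparison, convergence reports and NMR-profile fits.

The mutant comparison follows the convention used for simulated
folding/control run pairs: per-residue helicity deltas carry the combined
run-to-run uncertainty sqrt(u_a^2 + u_b^2); a residue window (defaults:
the three p53-TAD helix segments 18-27, 40-44, 48-52) is flagged as
"modulated" when the magnitude of its mean delta exceeds the combined
window uncertainty times a configurable multiplier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import Ensemble, HELIX_WINDOWS
from .local_structure import (HelicityProfile, ensemble_helicity,
                              profile_rmsd)
from .tertiary_structure import (ContactMap, contact_map, map_correlation,
                                 map_rmsd, distance_distribution)

__all__ = [
    "WindowDelta", "ComparisonReport", "delta_helicity",
    "compare_ensembles", "convergence_report", "rdc_scale_fit",
    "secondary_shift",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = HELIX_WINDOWS


@dataclass(frozen=True)
class WindowDelta:
    """Summary of one residue window in a pairwise comparison."""
    window: tuple[int, int]
    delta: float             # mean (b - a) helicity over the window
    uncertainty: float       # combined window uncertainty
    flagged: bool


@dataclass(frozen=True)
class ComparisonReport:
    """Helicity (and optionally contact-map) differences between two
    ensembles, b relative to a."""
    label_a: str
    label_b: str
    residue_numbers: np.ndarray
    delta: np.ndarray
    delta_uncertainty: np.ndarray
    windows: tuple[WindowDelta, ...]
    contact_delta: np.ndarray | None = None
    map_correlation: float | None = None
    map_rmsd: float | None = None

    @property
    def flagged_windows(self) -> tuple[tuple[int, int], ...]:
        return tuple(w.window for w in self.windows if w.flagged)

    def to_dict(self) -> dict:
        out = {
            "labels": [self.label_a, self.label_b],
            "residues": self.residue_numbers.tolist(),
            "delta_helicity": self.delta.tolist(),
            "delta_uncertainty": self.delta_uncertainty.tolist(),
            "windows": [{"window": list(w.window), "delta": w.delta,
                         "uncertainty": w.uncertainty,
                         "flagged": w.flagged} for w in self.windows],
        }
        if self.map_correlation is not None:
            out["contact_map_correlation"] = self.map_correlation
            out["contact_map_rmsd"] = self.map_rmsd
        return out


def delta_helicity(a: HelicityProfile, b: HelicityProfile,
                   windows=DEFAULT_WINDOWS,
                   flag_multiplier: float = 1.0,
                   label_a: str = "a", label_b: str = "b"
                   ) -> ComparisonReport:
    """Per-residue helicity difference b - a with combined uncertainty.

    Window uncertainty is the mean per-residue uncertainty of each profile
    over the window, combined in quadrature; a window is flagged when
    |mean delta| > flag_multiplier x combined uncertainty.  The report is
    antisymmetric under swapping a and b."""
    if not np.array_equal(a.residue_numbers, b.residue_numbers):
        raise ValueError("profiles cover different residue ranges")
    delta = b.fraction - a.fraction
    unc = np.sqrt(a.uncertainty ** 2 + b.uncertainty ** 2)
    wins = []
    nums = a.residue_numbers
    for lo, hi in windows:
        mask = (nums >= lo) & (nums <= hi)
        if not mask.any():
            raise ValueError(f"window {lo}-{hi} outside profile range")
        wdelta = float(delta[mask].mean())
        wu = float(np.sqrt(a.uncertainty[mask].mean() ** 2
                           + b.uncertainty[mask].mean() ** 2))
        wins.append(WindowDelta(window=(lo, hi), delta=wdelta,
                                uncertainty=wu,
                                flagged=abs(wdelta) > flag_multiplier * wu))
    return ComparisonReport(label_a=label_a, label_b=label_b,
                            residue_numbers=nums, delta=delta,
                            delta_uncertainty=unc, windows=tuple(wins))


def compare_ensembles(a: Ensemble, b: Ensemble,
                      a_runs: tuple[Ensemble, Ensemble] | None = None,
                      b_runs: tuple[Ensemble, Ensemble] | None = None,
                      windows=DEFAULT_WINDOWS,
                      flag_multiplier: float = 1.0,
                      backend: str = "ca-torsion",
                      contact_mode: str = "CA") -> ComparisonReport:
    """Full two-ensemble comparison: helicity deltas per window plus the
    contact-map difference metrics.  Pass ``a_runs``/``b_runs`` (pairs of
    independent runs) to obtain run-to-run uncertainties."""
    from .local_structure import merge_runs

    def profile_of(ens, runs):
        if runs is not None:
            return merge_runs(ensemble_helicity(runs[0], backend),
                              ensemble_helicity(runs[1], backend))
        return ensemble_helicity(ens, backend)

    pa = profile_of(a, a_runs)
    pb = profile_of(b, b_runs)
    report = delta_helicity(pa, pb, windows, flag_multiplier,
                            label_a=a.label or "a", label_b=b.label or "b")
    ma = contact_map(a, mode=contact_mode)
    mb = contact_map(b, mode=contact_mode)
    try:
        corr = map_correlation(ma, mb)
    except ValueError:
        corr = float("nan")
    return ComparisonReport(
        label_a=report.label_a, label_b=report.label_b,
        residue_numbers=report.residue_numbers, delta=report.delta,
        delta_uncertainty=report.delta_uncertainty,
        windows=report.windows,
        contact_delta=mb.matrix - ma.matrix,
        map_correlation=corr, map_rmsd=map_rmsd(ma, mb))


def convergence_report(run1: Ensemble, run2: Ensemble,
                       backend: str = "ca-torsion",
                       contact_mode: str = "CA",
                       distance_pairs=("end-to-end",),
                       bin_width: float = 2.0) -> dict:
    """Agreement metrics between two independent runs of one system:
    helicity-profile RMSD, contact-map correlation and RMSD, and overlap
    of selected distance distributions."""
    if run1.topology.residues != run2.topology.residues:
        raise ValueError("runs have different topologies")
    p1 = ensemble_helicity(run1, backend)
    p2 = ensemble_helicity(run2, backend)
    m1 = contact_map(run1, mode=contact_mode)
    m2 = contact_map(run2, mode=contact_mode)
    try:
        corr = map_correlation(m1, m2)
    except ValueError:
        corr = float("nan")
    overlaps = {}
    nums = run1.topology.residue_numbers
    index = {int(n): k for k, n in enumerate(nums)}
    ca1, ca2 = run1.ca_coordinates(), run2.ca_coordinates()
    for pair in distance_pairs:
        if pair == "end-to-end":
            i, j = int(nums[0]), int(nums[-1])
        else:
            i, j = int(pair[0]), int(pair[1])
        d1 = np.linalg.norm(ca1[:, index[i]] - ca1[:, index[j]], axis=-1)
        d2 = np.linalg.norm(ca2[:, index[i]] - ca2[:, index[j]], axis=-1)
        lo = np.floor(min(d1.min(), d2.min()) / bin_width) * bin_width
        hi = np.ceil(max(d1.max(), d2.max()) / bin_width) * bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        h1, _ = np.histogram(d1, bins=edges, weights=run1.frame_weights)
        h2, _ = np.histogram(d2, bins=edges, weights=run2.frame_weights)
        overlaps[str(pair)] = float(np.minimum(h1, h2).sum())
    return {
        "labels": [run1.label or "run1", run2.label or "run2"],
        "helicity_profile_rmsd": profile_rmsd(p1, p2),
        "contact_map_correlation": corr,
        "contact_map_rmsd": map_rmsd(m1, m2),
        "distance_overlap": overlaps,
    }


def rdc_scale_fit(predicted, experimental
                  ) -> tuple[float, np.ndarray, float]:
    """Uniform scaling of a back-calculated residual-dipolar-coupling
    profile onto experiment: the least-squares scalar s minimising
    sum (s * pred - exp)^2, the scaled profile, and their Pearson r."""
    pred = np.asarray(predicted, float)
    exp = np.asarray(experimental, float)
    if pred.shape != exp.shape:
        raise ValueError("profiles have different lengths")
    keep = ~(np.isnan(pred) | np.isnan(exp))
    p, e = pred[keep], exp[keep]
    if p.size < 2:
        raise ValueError("need at least 2 overlapping residues")
    denom = float(p @ p)
    if denom == 0.0:
        raise ValueError("predicted profile is all zero; scale undefined")
    s = float(p @ e) / denom
    scaled = s * pred
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(p, e)[0, 1])
    return s, scaled, r


def secondary_shift(observed: pd.DataFrame,
                    coil_reference: dict | pd.Series) -> pd.DataFrame:
    """Secondary chemical shifts: observed minus residue-type random-coil
    reference.

    ``observed`` columns: residue, residue_type (one-letter), shift.
    Missing observations (NaN) propagate; a residue type absent from the
    reference is a hard error naming the type.  Negative Halpha secondary
    shifts indicate helical propensity."""
    obs = observed.rename(columns=str.lower)
    for col in ("residue", "residue_type", "shift"):
        if col not in obs:
            raise ValueError(f"observed table lacks column {col!r}")
    ref = dict(coil_reference)
    missing = sorted({t for t in obs["residue_type"].unique()
                      if t not in ref})
    if missing:
        raise ValueError(
            f"residue type {missing[0]!r} missing from coil reference")
    delta = obs["shift"] - obs["residue_type"].map(ref)
    return pd.DataFrame({"residue": obs["residue"],
                         "residue_type": obs["residue_type"],
                         "secondary_shift": delta})
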