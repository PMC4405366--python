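"""Paramagnetic relaxation enhancement (PRE) back-calculation.

Predicts per-residue HSQC intensity ratios I_ox/I_red for a nitroxide
spin label attached at a chosen site.  The transverse relaxation
enhancement of an amide proton at effective electron-proton distance r is

    R2sp = (K / r^6) * (4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2))

with K = 1.23e-32 cm^6 s^-2 for a single electron-proton pair, and the
observable intensity ratio is

    I_ox / I_red = R2 * exp(-R2sp * t) / (R2 + R2sp)

where R2 is the diamagnetic transverse relaxation rate and t the INEPT
delay of the HSQC experiment.  Since simulated ensembles carry no explicit
spin-label atom, C-alpha to C-alpha distances stand in for the
electron-proton separation, and the ensemble average is taken either as
<r^-6>^(-1/6) (the PRE-weighted mean, default) or as the plain <r>.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .ensemble_io import Ensemble

__all__ = [
    "PREParameters", "SpinLabelSite", "PREProfile",
    "effective_distance", "pre_ratio", "pre_profile",
    "profile_correlation", "DEFAULT_SITES",
]

CM_PER_ANGSTROM = 1e-8

#: spin-label attachment sites characterised experimentally for p53-TAD
DEFAULT_SITES = ("D7C", "E28C", "A39C", "D61C")


@dataclass(frozen=True)
class PREParameters:
    """Constants of the intensity-ratio equation (defaults: the 600 MHz
    p53-TAD experiment)."""
    K: float = 1.23e-32            # cm^6 s^-2, electron-proton interaction
    tau_c: float = 3.3e-9          # s, effective correlation time
    larmor_frequency: float = 6.0e8  # Hz, proton Larmor frequency
    R2_dia: float = 16.0           # s^-1, diamagnetic R2
    t_inept: float = 9.8e-3        # s, INEPT delay
    omega_convention: str = "angular"  # 'angular': omega = 2 pi nu

    def __post_init__(self):
        for name in ("K", "tau_c", "larmor_frequency", "R2_dia", "t_inept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_convention not in ("angular", "linear"):
            raise ValueError("omega_convention must be 'angular' or 'linear'")

    @property
    def omega_h(self) -> float:
        """Proton Larmor frequency in the chosen convention (rad/s or 1/s)."""
        if self.omega_convention == "angular":
            return 2.0 * np.pi * self.larmor_frequency
        return self.larmor_frequency

    @property
    def spectral_bracket(self) -> float:
        """4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2), in seconds."""
        wt = self.omega_h * self.tau_c
        return 4.0 * self.tau_c + 3.0 * self.tau_c / (1.0 + wt * wt)


@dataclass(frozen=True)
class SpinLabelSite:
    """A cysteine-substituted spin-label attachment site, e.g. E28C."""
    residue_number: int
    name: str = ""

    @classmethod
    def from_name(cls, name: str) -> "SpinLabelSite":
        """Parse 'E28C' style site names."""
        return cls(residue_number=int(name[1:-1]), name=name)


@dataclass(frozen=True)
class PREProfile:
    """Predicted per-residue intensity ratios for one label site.  The
    labeled residue itself is reported as 0 by convention (its own amide is
    fully broadened) and excluded from correlations."""
    residue_numbers: np.ndarray
    ratios: np.ndarray
    site: SpinLabelSite
    averaging_mode: str = "r6"

    def __post_init__(self):
        r = np.asarray(self.ratios, float)
        nums = np.asarray(self.residue_numbers, int)
        at_site = nums == self.site.residue_number
        if ((r[~at_site] <= 0) | (r[~at_site] > 1)).any():
            raise ValueError("intensity ratios must lie in (0, 1]")
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "residue_numbers", nums)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_numbers,
                             "intensity_ratio": self.ratios})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def effective_distance(ensemble: Ensemble, site: SpinLabelSite,
                       target_residue: int, mode: str = "r6") -> float:
    """Ensemble-averaged label-to-residue CA-CA distance in Angstrom.

    ``r6`` returns <r^-6>^(-1/6) over weighted frames (dominated by close
    approaches, as PRE itself is); ``arithmetic`` returns <r>."""
    if mode not in ("r6", "arithmetic"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    if target_residue == site.residue_number:
        raise ValueError("target residue coincides with the label site")
    ca = ensemble.ca_coordinates()
    numbers = ensemble.topology.residue_numbers
    index = {int(n): k for k, n in enumerate(numbers)}
    d = np.linalg.norm(ca[:, index[site.residue_number]]
                       - ca[:, index[int(target_residue)]], axis=-1)
    w = ensemble.frame_weights
    if mode == "arithmetic":
        return float(w @ d)
    return float((w @ d ** -6.0) ** (-1.0 / 6.0))


def pre_ratio(r, params: PREParameters = PREParameters()) -> np.ndarray:
    """Intensity ratio I_ox/I_red for effective distance(s) r in Angstrom.

    Strictly increasing in r, approaching 1 at large separation and 0 at
    contact."""
    r = np.asarray(r, float)
    if (r <= 0).any():
        raise ValueError("distances must be positive")
    r_cm = r * CM_PER_ANGSTROM
    r2sp = params.K / r_cm ** 6 * params.spectral_bracket
    out = (params.R2_dia * np.exp(-r2sp * params.t_inept)
           / (params.R2_dia + r2sp))
    return out if out.ndim else float(out)


def pre_profile(ensemble: Ensemble, site: SpinLabelSite,
                params: PREParameters = PREParameters(),
                mode: str = "r6") -> PREProfile:
    """Predicted intensity-ratio profile over every residue of the
    ensemble; the label site is set to 0."""
    numbers = ensemble.topology.residue_numbers
    if site.residue_number not in numbers:
        raise ValueError(f"label site residue {site.residue_number} "
                         "not in topology")
    ratios = np.zeros(numbers.size)
    for k, num in enumerate(numbers):
        if int(num) == site.residue_number:
            continue
        r_eff = effective_distance(ensemble, site, int(num), mode)
        ratios[k] = pre_ratio(r_eff, params)
    return PREProfile(residue_numbers=numbers, ratios=ratios, site=site,
                      averaging_mode=mode)


def profile_correlation(predicted: PREProfile,
                        experimental: pd.DataFrame) -> float:
    """Pearson correlation between a predicted profile and an experimental
    per-residue table (columns: residue, intensity_ratio; missing entries
    NaN or absent).  The label site is dropped from the comparison."""
    exp = experimental.rename(columns=str.lower)
    if "residue" not in exp or "intensity_ratio" not in exp:
        raise ValueError(
            "experimental table needs 'residue' and 'intensity_ratio' "
            "columns")
    merged = predicted.to_frame().merge(
        exp[["residue", "intensity_ratio"]], on="residue",
        suffixes=("_pred", "_exp")).dropna()
    merged = merged[merged["residue"] != predicted.site.residue_number]
    if len(merged) < 3:
        raise ValueError("fewer than 3 overlapping residues")
    x = merged["intensity_ratio_pred"].to_numpy()
    y = merged["intensity_ratio_exp"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(pearsonr(x, y).statistic)
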