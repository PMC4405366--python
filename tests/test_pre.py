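"""PRE intensity-ratio back-calculation against an independent oracle."""
import numpy as np
import pandas as pd
import pytest

from tadens import (Ensemble, PREParameters, SpinLabelSite, Topology,
                    effective_distance, pre_profile, pre_ratio,
                    profile_correlation)


def oracle_ratio(r_angstrom, K=1.23e-32, tau_c=3.3e-9, nu=6.0e8,
                 R2=16.0, t=9.8e-3, angular=True):
    """Scalar reference written directly from the intensity-ratio closed
    form, with explicit Angstrom-to-cm conversion."""
    import math
    r_cm = r_angstrom * 1e-8
    omega = 2.0 * math.pi * nu if angular else nu
    bracket = 4.0 * tau_c + 3.0 * tau_c / (1.0 + (omega * tau_c) ** 2)
    r2sp = K / r_cm ** 6 * bracket
    return R2 * math.exp(-r2sp * t) / (R2 + r2sp)


def test_matches_oracle_at_random_distances(rng):
    params = PREParameters()
    for r in rng.uniform(5.0, 60.0, size=50):
        assert pre_ratio(r, params) == pytest.approx(oracle_ratio(r),
                                                     rel=1e-10)


def test_linear_convention_also_matches_oracle(rng):
    params = PREParameters(omega_convention="linear")
    for r in rng.uniform(5.0, 60.0, size=10):
        assert pre_ratio(r, params) == pytest.approx(
            oracle_ratio(r, angular=False), rel=1e-10)


def test_limits_and_monotonicity():
    params = PREParameters()
    assert pre_ratio(1e6, params) == pytest.approx(1.0, abs=1e-6)
    assert pre_ratio(1.0, params) < 1e-6
    # strictly increasing wherever the ratio is representable in double
    # precision (below ~3.6 A the exponential underflows to exactly 0)
    grid = np.linspace(4.0, 150.0, 1000)
    vals = pre_ratio(grid, params)
    assert (np.diff(vals) > 0).all()
    coarse = pre_ratio(np.linspace(1.0, 100.0, 1000), params)
    assert (np.diff(coarse) >= 0).all()
    with pytest.raises(ValueError):
        pre_ratio(-1.0, params)


def test_fifteen_angstrom_reference_value():
    # hand evaluation of the closed form at 15 A with default constants
    assert pre_ratio(15.0, PREParameters()) == pytest.approx(0.459, abs=0.005)


def test_spectral_bracket_dominated_by_first_term():
    p = PREParameters()
    wt = p.omega_h * p.tau_c
    second = 3.0 * p.tau_c / (1.0 + wt * wt)
    assert second < 0.01 * 4.0 * p.tau_c
    assert p.spectral_bracket == pytest.approx(4.0 * p.tau_c + second)


def _two_frame_ensemble():
    topo = Topology.from_sequence("AC")
    coords = np.zeros((2, 2, 3))
    coords[0, 1, 0] = 10.0
    coords[1, 1, 0] = 20.0
    return Ensemble(topology=topo, coordinates=coords)


def test_effective_distance_closed_form():
    ens = _two_frame_ensemble()
    site = SpinLabelSite(1)
    r6 = effective_distance(ens, site, 2, "r6")
    expected = (0.5 * 10.0 ** -6 + 0.5 * 20.0 ** -6) ** (-1 / 6)
    assert r6 == pytest.approx(expected, rel=1e-12)
    arith = effective_distance(ens, site, 2, "arithmetic")
    assert arith == pytest.approx(15.0)
    assert r6 <= arith   # power-mean inequality


def test_effective_distance_single_frame_both_modes(rng):
    topo = Topology.from_sequence("ACD")
    coords = rng.uniform(-5, 5, size=(1, 3, 3))
    ens = Ensemble(topology=topo, coordinates=coords)
    site = SpinLabelSite(1)
    d = np.linalg.norm(coords[0, 0] - coords[0, 2])
    assert effective_distance(ens, site, 3, "r6") == pytest.approx(d)
    assert effective_distance(ens, site, 3, "arithmetic") == \
        pytest.approx(d)
    with pytest.raises(ValueError):
        effective_distance(ens, site, 1)


def test_profile_on_rigid_extended_chain_monotone():
    topo = Topology.from_sequence("A" * 20)
    coords = np.zeros((1, 20, 3))
    coords[0, :, 0] = np.arange(20) * 3.8
    ens = Ensemble(topology=topo, coordinates=coords)
    prof = pre_profile(ens, SpinLabelSite(1, "A1C"))
    assert prof.ratios[0] == 0.0          # label site by convention
    assert (np.diff(prof.ratios[1:]) > 0).all()


def test_profile_equals_scalar_oracle_on_rigid_structure(rng):
    topo = Topology.from_sequence("ACDEFGHIKL")
    coords = rng.uniform(-12, 12, size=(1, 10, 3))
    ens = Ensemble(topology=topo, coordinates=coords)
    site = SpinLabelSite(3)
    prof = pre_profile(ens, site)
    for k, num in enumerate(ens.topology.residue_numbers):
        if num == 3:
            continue
        d = np.linalg.norm(coords[0, 2] - coords[0, k])
        assert prof.ratios[k] == pytest.approx(oracle_ratio(d), rel=1e-10)


def test_r6_profile_never_above_arithmetic(small_wt_ensemble):
    ens, _ = small_wt_ensemble
    site = SpinLabelSite(28, "E28C")
    r6 = pre_profile(ens, site, mode="r6")
    ar = pre_profile(ens, site, mode="arithmetic")
    mask = r6.residue_numbers != 28
    assert (r6.ratios[mask] <= ar.ratios[mask] + 1e-12).all()


def test_contact_bias_produces_pre_dip():
    from tadens import ContactBias, SyntheticSpec, generate, p53_tad_fixture
    topo = p53_tad_fixture()
    p = np.zeros(61)
    biased_spec = SyntheticSpec(
        topology=topo, helix_propensity=p, n_frames=800, seed=21,
        contact_biases=(ContactBias(28, 50, 0.6, strength=4.0),))
    control_spec = SyntheticSpec(topology=topo, helix_propensity=p,
                                 n_frames=800, seed=21)
    biased, _ = generate(biased_spec)
    control, _ = generate(control_spec)
    site = SpinLabelSite(28, "E28C")
    pb = pre_profile(biased, site)
    pc = pre_profile(control, site)
    k = list(pb.residue_numbers).index(50)
    assert pb.ratios[k] < pc.ratios[k]


def test_profile_correlation_identity_and_inversion(small_wt_ensemble):
    ens, _ = small_wt_ensemble
    prof = pre_profile(ens, SpinLabelSite(28, "E28C"))
    table = prof.to_frame()
    assert profile_correlation(prof, table) == pytest.approx(1.0)
    inverted = table.assign(intensity_ratio=1.0 - table["intensity_ratio"])
    assert profile_correlation(prof, inverted) == pytest.approx(-1.0)


def test_profile_correlation_noise_attenuation(small_wt_ensemble, rng):
    """Correlation with a noisy copy stays near the attenuation expected
    from the noise model: rho = sigma_x / sqrt(sigma_x^2 + sigma^2)."""
    ens, _ = small_wt_ensemble
    prof = pre_profile(ens, SpinLabelSite(28, "E28C"))
    mask = prof.residue_numbers != 28
    sigma = 0.05
    x = prof.ratios[mask]
    expected = x.std() / np.sqrt(x.std() ** 2 + sigma ** 2)
    corrs = []
    for _ in range(30):
        noisy = prof.to_frame()
        noisy.loc[mask, "intensity_ratio"] += rng.normal(
            0, sigma, mask.sum())
        corrs.append(profile_correlation(prof, noisy))
    se = np.std(corrs) / np.sqrt(len(corrs))
    assert abs(np.mean(corrs) - expected) < 3 * max(se, 0.01)


def test_profile_correlation_requires_overlap(small_wt_ensemble):
    ens, _ = small_wt_ensemble
    prof = pre_profile(ens, SpinLabelSite(28, "E28C"))
    tiny = pd.DataFrame({"residue": [1, 2], "intensity_ratio": [0.5, 0.6]})
    with pytest.raises(ValueError, match="3 overlapping"):
        profile_correlation(prof, tiny)
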