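"""Synthetic-ensemble generator: ground truth, geometry, contact biases.

The enumeration oracle used here (see conftest) is written independently
of the package: it walks all helix/coil patterns of a short segment with
itertools, applies the minimum-run rule by string scanning, and
accumulates exact expectations.
"""
import numpy as np
import pytest

from tadens import (ContactBias, SyntheticSpec, Topology, assign_helix,
                    build_coordinates, generate, p53_tad_fixture,
                    sample_states, wild_type_like_spec)
from tadens.synthetic_ensembles import (CA_BOND, enforce_min_run,
                                        expected_helicity,
                                        propensity_for_target)

from conftest import oracle_relabeled_expectations


def test_package_enumeration_matches_independent_oracle():
    for p in (0.05, 0.10, 0.25, 0.50):
        ours = expected_helicity([p] * 8)
        theirs, _, _ = oracle_relabeled_expectations([p] * 8)
        assert np.allclose(ours, theirs, atol=1e-12)


# --- sample_states -------------------------------------------------------

def test_zero_and_full_propensity(wt_topology):
    zero = SyntheticSpec(topology=wt_topology,
                         helix_propensity=np.zeros(61), n_frames=50, seed=0)
    assert not sample_states(zero).any()
    p = np.zeros(61)
    p[17:27] = 1.0     # residues 18-27
    full = SyntheticSpec(topology=wt_topology, helix_propensity=p,
                         n_frames=20, seed=0)
    states = sample_states(full)
    assert states[:, 17:27].all()
    assert not states[:, :17].any() and not states[:, 27:].any()


def test_min_run_relabeling():
    # H,H,C,H,H -> all coil under the >=3 rule
    states = np.array([[1, 1, 0, 1, 1]])
    assert not enforce_min_run(states).any()
    assert enforce_min_run(np.array([[1, 1, 1, 0, 1]]))[0].tolist() == \
        [1, 1, 1, 0, 0]


def test_marginal_matches_enumeration_oracle(wt_topology):
    p = np.zeros(61)
    p[17:27] = 0.10
    spec = SyntheticSpec(topology=wt_topology, helix_propensity=p,
                         n_frames=4000, seed=42)
    states = sample_states(spec)
    site_exp, mean_e, var_frame = oracle_relabeled_expectations([0.10] * 10)
    region = states[:, 17:27].mean()
    se = np.sqrt(var_frame / 4000)
    assert abs(region - mean_e) < 3 * se


def test_cooperativity_extends_runs(wt_topology):
    p = np.full(61, 0.10)
    flat = SyntheticSpec(topology=wt_topology, helix_propensity=p,
                         n_frames=2000, seed=1)
    coop = SyntheticSpec(topology=wt_topology, helix_propensity=p,
                         cooperativity=2.0, n_frames=2000, seed=1)
    h_flat = sample_states(flat).mean()
    h_coop = sample_states(coop).mean()
    assert h_coop > h_flat  # cooperative extension survives the run rule


# --- build_coordinates ---------------------------------------------------

def test_all_helical_rise(wt_topology):
    """A fully helical 20-residue stretch spans ~1.5 A rise per residue."""
    seq_topo = Topology.from_sequence("A" * 20)
    spec = SyntheticSpec(topology=seq_topo, helix_propensity=np.ones(20),
                         n_frames=5, seed=0, torsion_jitter=0.0)
    states = sample_states(spec)
    ens = build_coordinates(states, spec)
    e2e = np.linalg.norm(ens.coordinates[:, -1] - ens.coordinates[:, 0],
                         axis=-1)
    expected = 1.5 * 19
    assert np.all(np.abs(e2e - expected) < 0.15 * expected)


def test_excluded_volume_enforced(wt_topology):
    seq_topo = Topology.from_sequence("A" * 20)
    spec = SyntheticSpec(topology=seq_topo, helix_propensity=np.zeros(20),
                         excluded_volume_radius=4.0, n_frames=50, seed=3)
    ens = build_coordinates(sample_states(spec), spec)
    x = ens.coordinates
    iu = np.triu_indices(20, 2)
    dmin = np.sqrt(np.sum(
        (x[:, iu[0]] - x[:, iu[1]]) ** 2, axis=-1)).min()
    assert dmin >= 4.0


def test_bond_lengths_exact(small_wt_ensemble):
    ens, _ = small_wt_ensemble
    bonds = np.linalg.norm(np.diff(ens.coordinates, axis=1), axis=-1)
    assert np.allclose(bonds, CA_BOND, atol=1e-9)


def test_contact_bias_calibration_hits_target():
    spec = wild_type_like_spec(
        n_frames=4000, seed=1,
        contact_biases=[ContactBias(10, 50, 0.15)])
    _, truth = generate(spec)
    assert abs(truth.contact_frequencies[(10, 50)] - 0.15) <= 0.05


def test_contact_bias_monotone_in_strength():
    topo = p53_tad_fixture()
    p = np.zeros(61)
    realized = []
    for s in (0.0, 1.5, 3.0):
        spec = SyntheticSpec(
            topology=topo, helix_propensity=p, n_frames=600, seed=7,
            contact_biases=(ContactBias(10, 40, 0.5, strength=s),))
        _, truth = generate(spec)
        realized.append(truth.contact_frequencies[(10, 40)])
    assert realized[0] < realized[1] < realized[2]


def test_contact_pair_separation_validated():
    with pytest.raises(ValueError, match=r"\|i-j\| >= 4"):
        ContactBias(10, 12, 0.1)


# --- generate ------------------------------------------------------------

def test_generate_deterministic():
    e1, t1 = generate(wild_type_like_spec(n_frames=100, seed=9))
    e2, t2 = generate(wild_type_like_spec(n_frames=100, seed=9))
    assert np.array_equal(e1.coordinates, e2.coordinates)
    assert np.array_equal(t1.states, t2.states)


def test_generate_single_frame():
    ens, truth = generate(wild_type_like_spec(n_frames=1, seed=4))
    assert ens.n_frames == 1 and truth.states.shape[0] == 1
    assert np.array_equal(truth.realized_helicity, truth.states.mean(0))


def test_wild_type_preset_helicity_confined_to_segments(small_wt_ensemble):
    _, truth = small_wt_ensemble
    h = truth.realized_helicity
    segs = np.zeros(61, bool)
    for lo, hi in ((18, 27), (40, 44), (48, 52)):
        segs[lo - 1:hi] = True
    assert (h[~segs] == 0).all()
    assert h[segs].sum() > 0


def test_ground_truth_matches_torsion_assignment(small_wt_ensemble):
    """The generator and the torsion-based assignment share one helix
    definition, so ground truth is recovered exactly."""
    ens, truth = small_wt_ensemble
    states = assign_helix(ens, "ca-torsion")
    assert np.array_equal(states, truth.states)


def test_backbone_mode_matches_phi_psi_assignment():
    spec = wild_type_like_spec(n_frames=150, seed=13,
                               backbone_mode="N-CA-C")
    ens, truth = generate(spec)
    assert ens.n_atoms == 3 * 61
    states = assign_helix(ens, "phi-psi")
    assert np.array_equal(states, truth.states)


def test_propensity_for_target_inverts_enumeration():
    for target in (0.05, 0.10):
        p = propensity_for_target(target, 10)
        realized = expected_helicity([p] * 10).mean()
        assert abs(realized - target) < 1e-9
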