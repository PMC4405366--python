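"""Contact maps, distance distributions and radius of gyration."""
import numpy as np
import pytest

from tadens import (Ensemble, Topology, contact_map, distance_distribution,
                    map_correlation, map_rmsd, radius_of_gyration,
                    AtomSelection)
from tadens.tertiary_structure import ContactMap

from conftest import make_toy_ensemble


def brute_force_contact_map(ensemble, cutoff, mode, min_sep):
    """Independent double-loop reference over frames and atom pairs."""
    topo = ensemble.topology
    n_res = topo.n_residues
    numbers = topo.residue_numbers
    heavy = [[k for k, (nm, ridx, el) in enumerate(topo.atoms)
              if ridx == r and (el != "H")] for r in range(n_res)]
    ca = [[k for k, (nm, ridx, el) in enumerate(topo.atoms)
           if ridx == r and nm == "CA"] for r in range(n_res)]
    groups = ca if mode == "CA" else heavy
    mat = np.full((n_res, n_res), np.nan)
    w = ensemble.frame_weights
    for i in range(n_res):
        for j in range(n_res):
            if abs(i - j) < min_sep:
                continue
            total = 0.0
            for f in range(ensemble.n_frames):
                dmin = np.inf
                for ai in groups[i]:
                    for aj in groups[j]:
                        d = np.linalg.norm(ensemble.coordinates[f, ai]
                                           - ensemble.coordinates[f, aj])
                        dmin = min(dmin, d)
                if dmin <= cutoff:
                    total += w[f]
            mat[i, j] = total
    return mat


def test_contact_map_equals_brute_force(rng):
    ens = make_toy_ensemble(rng, n_res=7, n_frames=20, spread=7.0)
    for mode in ("CA", "min-heavy-atom"):
        cm = contact_map(ens, cutoff=6.0, mode=mode, min_sep=2)
        ref = brute_force_contact_map(ens, 6.0, mode, 2)
        assert np.allclose(cm.matrix, ref, equal_nan=True)


def test_contact_boundary_inclusive():
    """A pair at exactly the cutoff counts as a contact."""
    topo = Topology.from_sequence("ACDEF")
    coords = np.zeros((1, 5, 3))
    coords[0, :, 0] = [0.0, 10.0, 20.0, 30.0, 4.2]
    ens = Ensemble(topology=topo, coordinates=coords)
    cm = contact_map(ens, cutoff=4.2, mode="CA", min_sep=4)
    assert cm.matrix[0, 4] == 1.0


def test_extended_chain_all_zero(rng):
    topo = Topology.from_sequence("A" * 20)
    coords = np.zeros((3, 20, 3))
    coords[:, :, 0] = np.arange(20) * 3.8
    ens = Ensemble(topology=topo, coordinates=coords)
    cm = contact_map(ens, cutoff=8.0, mode="CA", min_sep=4)
    vals = cm.upper_triangle()
    assert (vals == 0).all()


def test_contact_probability_monotone_in_cutoff(rng):
    ens = make_toy_ensemble(rng, n_res=8, n_frames=30, spread=8.0)
    small = contact_map(ens, cutoff=5.0, mode="CA", min_sep=4)
    large = contact_map(ens, cutoff=9.0, mode="CA", min_sep=4)
    assert (large.upper_triangle() >= small.upper_triangle()).all()


def test_map_metrics(rng):
    ens = make_toy_ensemble(rng, n_res=8, n_frames=40, spread=8.0)
    a = contact_map(ens, cutoff=8.0, mode="CA", min_sep=4)
    assert map_correlation(a, a) == pytest.approx(1.0)
    assert map_rmsd(a, a) == 0.0
    anti = ContactMap(residue_numbers=a.residue_numbers,
                      matrix=1.0 - a.matrix, cutoff=a.cutoff,
                      distance_mode=a.distance_mode,
                      min_sequence_separation=a.min_sequence_separation)
    assert map_correlation(a, anti) == pytest.approx(-1.0)
    shifted = ContactMap(residue_numbers=a.residue_numbers,
                         matrix=np.clip(a.matrix + 0.016, 0, 1),
                         cutoff=a.cutoff, distance_mode=a.distance_mode,
                         min_sequence_separation=a.min_sequence_separation)
    if (a.upper_triangle() <= 1 - 0.016).all():
        assert map_rmsd(a, shifted) == pytest.approx(0.016)


def test_map_correlation_zero_variance_error():
    topo = Topology.from_sequence("A" * 6)
    flat = ContactMap(residue_numbers=topo.residue_numbers,
                      matrix=np.where(
                          np.abs(np.subtract.outer(range(6), range(6))) < 4,
                          np.nan, 0.3),
                      cutoff=8.0, distance_mode="CA",
                      min_sequence_separation=4)
    with pytest.raises(ValueError, match="zero variance"):
        map_correlation(flat, flat)


def test_distance_distribution_mean_matches_brute_force(rng):
    ens = make_toy_ensemble(rng, n_res=6, n_frames=25, spread=9.0)
    dist = distance_distribution(ens, 1, 6, bin_width=0.5)
    d = np.linalg.norm(ens.coordinates[:, 0] - ens.coordinates[:, 5],
                       axis=-1)
    assert dist.mean == pytest.approx(d.mean(), rel=1e-9)
    assert dist.std == pytest.approx(d.std(), rel=1e-9)
    assert dist.frequencies.sum() == pytest.approx(1.0)


def test_distance_distribution_rigid_single_bin():
    topo = Topology.from_sequence("ACDEF")
    base = np.zeros((1, 5, 3))
    base[0, :, 0] = np.arange(5) * 3.8
    frames = np.concatenate([base + s for s in ([0, 0, 0], [5, 5, 5],
                                                [-3, 2, 9])])
    ens = Ensemble(topology=topo, coordinates=frames)
    dist = distance_distribution(ens, 1, 5, bin_width=1.0)
    assert (dist.frequencies > 0).sum() == 1


def test_distance_same_residue_error(rng):
    ens = make_toy_ensemble(rng)
    with pytest.raises(ValueError):
        distance_distribution(ens, 3, 3)


def test_helical_i_ip3_distance_mode(small_wt_ensemble):
    """Frames helical over 18-27 put the D21-K24 CA distance near the
    ideal-helix i,i+3 separation of ~5 A."""
    ens, truth = small_wt_ensemble
    helical_frames = truth.states[:, 17:27].all(axis=1)
    if helical_frames.sum() < 2:
        helical_frames = truth.states[:, 20] & truth.states[:, 23]
    sub = Ensemble(topology=ens.topology,
                   coordinates=ens.coordinates[helical_frames.astype(bool)])
    dist = distance_distribution(sub, 21, 24, bin_width=0.5)
    assert 4.0 < dist.mean < 6.5


def test_radius_of_gyration_closed_forms():
    topo = Topology.from_sequence("AC")
    coincident = Ensemble(topology=topo, coordinates=np.zeros((2, 2, 3)))
    rg, mean = radius_of_gyration(coincident)
    assert np.allclose(rg, 0.0) and mean == 0.0
    two = np.zeros((1, 2, 3))
    two[0, 1, 0] = 2.0
    ens = Ensemble(topology=topo, coordinates=two)
    rg, mean = radius_of_gyration(ens)
    assert mean == pytest.approx(1.0)


def test_radius_of_gyration_brute_force(rng):
    ens = make_toy_ensemble(rng, n_res=9, n_frames=12)
    rg, mean = radius_of_gyration(ens)
    for f in range(ens.n_frames):
        x = ens.coordinates[f]
        ref = np.sqrt(np.mean(np.sum((x - x.mean(0)) ** 2, axis=1)))
        assert rg[f] == pytest.approx(ref, rel=1e-9)
    assert mean == pytest.approx(rg.mean(), rel=1e-9)
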