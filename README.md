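# tadens

Ensemble analysis for the intrinsically disordered transactivation domain
(TAD, residues 1–61) of the tumor suppressor p53, and for disordered
chains like it.

Intrinsically disordered proteins are described by heterogeneous
conformational ensembles rather than a single fold.  Simulation studies
of p53-TAD characterise those ensembles through a standard battery of
observables — per-residue helicity and helical-substate distributions,
long-range contact probability maps, inter-residue distance
distributions, back-calculated paramagnetic relaxation enhancement (PRE)
profiles for site-directed spin labels, and fixed-radius clustering —
and quantify convergence by comparing independent runs, then ask how
cancer-associated mutations (K24N, E17D, W53G, D49Y, N29K/N30D) shift
the ensemble.  `tadens` implements that entire analysis battery as a
tested, reusable library plus CLI, together with a seeded synthetic
ensemble generator with known ground truth, so every stage can be
validated by parameter recovery even though the original trajectories
are not publicly deposited.

## What it computes

* **Ensemble I/O** — multi-model PDB (one MODEL per frame), atom/frame
  selections, the p53-TAD sequence fixture, point-mutation editing.
* **Helicity** — dihedral-based helix assignment (φ/ψ or Cα virtual
  torsion backends, minimum run of 3), per-residue profiles with
  run-to-run uncertainties, helical-substate (run start, run end)
  histograms, profile RMSD.
* **Tertiary structure** — contact maps (minimal heavy-atom ≤ 4.2 Å or
  Cα ≤ 8 Å, boundary inclusive, |i−j| ≥ 4), map correlation/RMSD,
  distance distributions, radius of gyration.
* **PRE** — intensity ratios I_ox/I_red from

      R2sp = (K/r⁶)(4τc + 3τc/(1 + ωH²τc²)),
      I_ox/I_red = R2 exp(−R2sp·t)/(R2 + R2sp)

  with K = 1.23×10⁻³² cm⁶s⁻², τc = 3.3 ns, ωH = 2π·600 MHz, R2 = 16 s⁻¹,
  t = 9.8 ms, Cα–Cα distances as the electron–proton proxy and
  ⟨r⁻⁶⟩^(−1/6) ensemble averaging (both choices switchable).
* **Clustering** — deterministic fixed-radius leader + refinement on
  superposed Cα RMSD (5 Å default), population summaries by size band.
* **Comparison** — wild-type vs mutant helicity deltas with significance
  flags, convergence reports between independent runs, RDC uniform
  scaling, secondary chemical shifts against a coil reference.
* **Synthetic ensembles** — seeded two-state helix/coil chains with
  cooperativity, excluded volume, and calibrated long-range contact
  biases; realised per-frame states are returned as ground truth.

See `docs/methods.md` for the model details, conventions and
limitations.

## Worked example

Two independent wild-type-like runs of 4000 frames, a K24N-like pair
(proximal helix target halved from 10% to 5%), and the closed-form PRE
reference value:

```python
from tadens import (generate, wild_type_like_spec, mutant_like_spec,
                    ensemble_helicity, merge_runs, region_mean_helicity,
                    delta_helicity, pre_ratio, PREParameters)

wt = [ensemble_helicity(generate(wild_type_like_spec(n_frames=4000, seed=s))[0])
      for s in (1, 2)]
mut = [ensemble_helicity(generate(mutant_like_spec({(18, 27): 0.05},
                                                   n_frames=4000, seed=s))[0])
       for s in (3, 4)]
wt_prof, mut_prof = merge_runs(*wt), merge_runs(*mut)
print(f"wild-type helicity 18-27: {100*region_mean_helicity(wt_prof, 18, 27):.1f}%")
report = delta_helicity(wt_prof, mut_prof, flag_multiplier=2.0)
for w in report.windows:
    mark = "  <- modulated" if w.flagged else ""
    print(f"window {w.window}: delta {100*w.delta:+.1f}% "
          f"(+/- {100*w.uncertainty:.1f}%){mark}")
print(f"PRE ratio at 15 A: {pre_ratio(15.0, PREParameters()):.3f}")
```

prints

```
wild-type helicity 18-27: 10.2%
window (18, 27): delta -5.4% (+/- 0.4%)  <- modulated
window (40, 44): delta +0.8% (+/- 1.2%)
window (48, 52): delta +0.6% (+/- 1.0%)
PRE ratio at 15 A: 0.459
```

The wild-type-like ensemble recovers its 10% design helicity over
residues 18–27; halving the proximal target produces a −5 percentage
point delta that clears twice its run-to-run uncertainty (flagged
"modulated"), while the two distal windows stay within noise — the
pattern expected for a mutation acting locally on the first partial
helix.  The PRE value is the intensity ratio a residue 15 Å from the
spin label would show under the default experimental constants.

The same workflow is available from the shell:

```sh
tadens --seed 1 generate --preset wild-type --n-frames 2000 --out out/
tadens helicity out/wild-type.pdb --out out/
tadens pre out/wild-type.pdb --out out/           # D7C E28C A39C D61C batch
tadens compare out/wild-type.pdb out/k24n.pdb --out out/
```

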