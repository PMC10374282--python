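# conformerkit

Multi-modal analysis of protein conformational heterogeneity and dynamics.

Large multi-domain proteins — dynamin-family GTPases are the motivating
case — often populate several conformers that exchange on microsecond
timescales.  No single solution technique resolves both the structures and
the kinetics: FRET and DEER report pairwise inter-label distances (30–80 Å
and 1.5–8 nm respectively), SAXS reports the average shape, neutron
spin-echo (NSE) bounds nanosecond shape dynamics, and filtered FCS (fFCS)
resolves the exchange-time spectrum.  conformerkit implements the analysis
chain that turns these measurements into a pair of conformer structures
(M1, M2) with population fractions and relaxation times:

* **labels** — accessible-volume (AV/ACV) simulation of dye and spin-label
  positions on bead models; inter-label distance distributions; FRET
  observables with κ² = 2/3:
  `E = Σᵢⱼ wᵢwⱼ (1 + (Rᵢⱼ/R₀)⁶)⁻¹`.
* **tcspc** — donor-decay forward models
  `f_D|D^(DA)(t) = f_D|D^(D0)(t)·ε_D(t)` with the FRET-induced donor decay
  `ε_D(t) = (1−x_DOnly)∫p(R)e^{−t k₀(R₀/R)⁶}dR + x_DOnly`, iterative
  reconvolution `g = N_F·f⊗IRF + N_BG·IRF + bg`, global Gaussian-mixture
  distance fits, maximum-entropy p(R) reconstruction, lifetime moments and
  static/dynamic FRET-lines.
* **deer** — dipolar kernel `K(t,R) = ∫₀¹cos[(3x²−1)ω_dd t]dx` with
  `ω_dd = 2π·52.04 MHz·nm³/R³`, exponential background correction,
  non-negative Tikhonov inversion with L-curve selection.
* **ffcs** — minimal-variance unbiased species filters, species auto/cross
  correlation, and a global diffusion×kinetics model with up to three
  relaxation times shared across label-pair variants.
* **nse** — rigid-body effective diffusion D₀(q) from a 6×6 diffusion
  tensor, the full intermediate-scattering-function model with a spherical
  harmonics rotational expansion (l ≤ 15), cumulant analysis, hydrodynamic
  corrections H_t = 1−c[η], 1−H_r = (1−H_t)/3 and the Debye–Waller MSD
  bound u = √(−3 ln(1−err))/q.
* **saxs** — Debye scattering of bead models, Guinier/Kratky reduction,
  concentration-series extrapolation, Percus–Yevick structure factor,
  χ² scoring with fitted scale/offset and two-state ensemble fits.
* **discriminate** — χ² scoring of candidate (M1, M2) pairs against label
  restraints and SAXS, p-value fusion by Fisher's method
  `X² = −2 ln(p_label·p_SAXS) ~ χ²₄`, pair selection at a confidence
  threshold, effective-dof estimation and ensemble-precision metrics
  (pairwise-distance SD, normalized precision, RMSF).
* **synthetic** — deterministic two-conformer toy systems and forward-
  simulated data for every modality, with ground truth attached.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a two-conformer system, invert one of its DEER traces, and run the
full discrimination:

```python
import numpy as np
from conformerkit import deer, saxs, synthetic
from conformerkit.discriminate import evaluate_candidates

system = synthetic.make_toy_system(seed=10)        # M1/M2, 0.61/0.39
bundle = synthetic.simulate_modalities(system, seed=10)

# DEER: background-correct and invert the first trace
trace = bundle["deer"]["traces"][0]
kernel = bundle["deer"]["kernel"]
form, k = deer.background_correct(trace, fit_start=2.5)
depth = 1.0 - float(np.median(form[kernel.t >= 3.0]))
signal = 1.0 - (1.0 - form) / depth
alpha, info = deer.l_curve_select(signal, kernel, np.logspace(-3, 1, 20))
p = info["solutions"][info["corner_index"]]
print(f"background k = {k:.3f} /us, <R_SS> = {p.mean():.2f} nm "
      f"(truth {bundle['deer']['truth'][0].mean():.2f} nm)")

# discrimination: truth pair + decoys against restraints and SAXS
cands = synthetic.candidate_ensemble(system, n_decoys=8, seed=10)
structures = {e["kind"]: e["structure"] for e in cands}
curves = {k_: saxs.debye_scatter(st, bundle["saxs"]["data"].q)
          for k_, st in structures.items()}
out = evaluate_candidates(structures, bundle["restraints"],
                          bundle["saxs"]["data"], curves, d_max=90.0)
best = max(out["accepted"], key=lambda s: s.p_combined)
print(f"accepted {len(out['accepted'])}/{len(out['scored'])} pairs; "
      f"best: ({best.m1_id}, {best.m2_id}) p = {best.p_combined:.3f}, "
      f"SAXS x_M1 = {best.saxs_fraction_m1:.2f}")
```

Output:

```
background k = 0.086 /us, <R_SS> = 3.82 nm (truth 3.89 nm)
accepted 1/45 pairs; best: (truth_m1, truth_m2) p = 1.000, SAXS x_M1 = 0.61
```

The DEER inversion recovers the mean inter-spin distance of the simulated
mixture to better than 0.1 nm; the meta-analysis keeps exactly the
generating conformer pair (at the combined p = 0.68 threshold) and its SAXS
mixture fraction matches the ground-truth population 0.61.

A thin CLI wraps the most common entry points:

```bash
conformerkit simulate out/ --seed 1        # synthetic bundle + truth.json
conformerkit fit-deer out/deer_00.dat      # Tikhonov inversion, JSON result
conformerkit score-saxs out/m1.pdb out/saxs.dat
```

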