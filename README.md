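# bindkin

Ligand binding and unbinding kinetics from Markov state models, with
exactly solvable synthetic benchmarks.

`bindkin` is for computational biophysicists who estimate binding
thermodynamics and kinetics of small molecules from trajectory data — the
kind of analysis used to characterize benzene binding to the engineered
cavity of T4 lysozyme L99A. It implements the full inference chain as a
library of composable estimators plus a config-driven CLI:

* **featurization** — binding-pocket definition (protein heavy atoms within
  a cutoff of the ligand in a holo structure), binary ligand–residue
  contacts, pocket–ligand center-of-mass distances, superposition RMSD,
  dual RMSD/distance bound-state labelling, transition-path-segment
  extraction;
* **model building** — tICA (scikit-learn-style transformer), k-means
  discretization, reversible maximum-likelihood MSMs with implied-timescale
  validation, and PCCA+/hidden-Markov coarse-graining into a few
  metastable macrostates;
* **kinetics** — mean first-passage times, on/off rates, standard binding
  free energies, activation barriers from transition-path times, bootstrap
  uncertainties;
* **transition path theory** — committors, reactive fluxes, ranked pathway
  decomposition;
* **biased sampling** — umbrella sampling + WHAM free-energy profiles, and
  infrequent well-tempered metadynamics with acceleration-factor rescaling
  and Poisson/Kolmogorov–Smirnov rate analysis;
* **synthetic ground truth** — Gillespie-sampled kinetic networks with
  analytic stationary/MFPT/committor oracles, overdamped Langevin dynamics
  on analytic landscapes, and state-conditioned feature emission, so every
  estimator is testable without molecular dynamics.

## The model in brief

Trajectories featurized as contact vectors are projected onto slow
collective coordinates by tICA (generalized eigenproblem
C_τ v = λ C_0 v), discretized into microstates, and summarized by a
reversible transition matrix T(τ) estimated by maximum likelihood under
detailed balance π_i T_ij = π_j T_ji. A hidden Markov model over a few
metastable macrostates (initialized from PCCA+) yields populations π and
lifetimes. Kinetics follow from mean first-passage times:

    k_on = 1 / (MFPT_on · C),        k_off = 1 / MFPT_off,
    ΔG = −k_B T ln(π_bound / π_unbound),   ΔG⁰ = ΔG + RT ln(C / 1 M),

with C the ligand concentration. Transition path theory decomposes the
reactive flux f_ij = π_i q⁻_i T_ij q⁺_j into pathways; the
transition-path-time relation k_off = (1/τ_TPT) e^{−ΔG*/RT} converts
barrier-crossing durations into activation free energies. Biased-sampling
modules recover free-energy profiles (WHAM) and unbinding rates
(infrequent metadynamics, rescaled time = simulated time × ⟨e^{V(s,t)/kT}⟩).

## Worked example

Desk-scale identities from published macrostate statistics (populations
99.83% bound / 0.11% unbound, C = 9.55 mM, T = 303 K, MFPTs 5163 ns /
3.2×10⁶ ns, τ_TPT = 7 ns, experimental k_off = 950 s⁻¹):

```python
>>> import bindkin as bk
>>> bk.binding_dG(0.9983, 0.0011, temperature=303.0, concentration=9.55e-3)
(-4.100904326242897, -6.901506595026419)     # (ΔG_sim, ΔG⁰) kcal/mol
>>> bk.rates_from_mfpt(5163.0, 3.2e6, 9.55e-3)
(20281239.954448335, 312.5)                  # k_on 1/(M·s), k_off 1/s
>>> bk.barrier_unbinding(7.0, 0.95e3, temperature=303.0)
(11.920893703296512, 7.177842399385068)      # ΔG*_unbinding in RT, kcal/mol
>>> bk.fold_change(2.21, temperature=303.0)
39.26554377285383                            # e^{ΔG/RT} population fold change
```

The first line says the simulated populations imply a standard (1 M)
binding free energy of −6.9 kcal/mol; the second converts the printed
MFPTs into k_on ≈ 2.0×10⁷ M⁻¹s⁻¹ and k_off ≈ 312 s⁻¹; the third infers an
11.9 RT unbinding barrier from a 7 ns transition-path time; the fourth is
the Boltzmann fold-change of a 2.21 kcal/mol helix-opening penalty (≈39).

End-to-end on the bundled four-state benchmark (25 trajectories × 40 000
frames at 0.1 ns; dynamics compressed 300× in time so binding and
unbinding are observable at this budget):

```python
>>> from bindkin.pipeline import run_pipeline
>>> report = run_pipeline({"seed": 1}, stages=("simulate", "msm", "kinetics"))
>>> report["macrostates"]["populations"]
[8.287546206445593e-05, 0.00047102355097339185,
 0.0007110369545795678, 0.9987350640323825]
>>> report["ground_truth"]["populations"]
[0.001100072604791956, 6.400422427874004e-05,
 0.0004700310220474621, 0.9983658921488818]
>>> report["kinetics"]["mfpt_on_ns"], report["kinetics"]["mfpt_off_ns"]
(11.450563420794644, 14884.834540300335)
>>> report["kinetics"]["dG0_kcal_mol"]
-7.166213943762821
```

The pipeline re-identifies the dominant bound state (0.9987 vs 0.9984
ground truth), the rare unbound state and both intermediates, and its
MFPTs bracket the network's analytic values (13.1 ns and 10 852 ns at this
time compression) within the scatter expected from the ~10
binding/unbinding events such an ensemble contains; the bootstrap block of
the report quantifies that scatter. The same run is available from the
shell:

```bash
bindkin -v kinetics --seed 1 --out results_dir
bindkin wham --barrier 4.8 --out results_dir       # double-well PMF by WHAM
bindkin metadyn --n-runs 15 --out results_dir      # escape-rate recovery
```

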