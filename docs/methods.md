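# Methods

## The transport model

Vibrational energy flow between residues is modelled as a linear master
equation over per-degree-of-freedom excess energies `E_j(t)`,

    dE_j/dt = Σ_i [ k_ij E_i(t) − k_ji E_j(t) ].

The model assumes diffusive (rate-equation) transport, appropriate for
heterogeneous biomolecular backbones; ballistic transport, seen in
repeating-unit chains such as alkanes, is outside its scope. All rates are
constant in time (no temperature-dependent transport), and intramolecular
rates are symmetric, `k_ij = k_ji`, so the uniform per-DOF energy
distribution (equipartition) is a stationary state of the closed system.

Three intramolecular edge classes are built from structure:

* **BB** — sequence neighbours `(i, i+1)`, rate `D_B / d²` with `d` the
  Cα–Cα distance. With the defaults this gives adjacent-residue transfer
  times of ~0.25 ps.
* **HB** — backbone hydrogen bonds between residues at least three apart in
  sequence, detected with a donor–acceptor N···O cutoff of 3.5 Å and an
  N–H···O angle of at least 120° (the amide H is inferred from N/CA/C
  geometry when absent). Rate `D_C / r^p` with `r` the N···O distance.
* **HC** — heater contacts: any heavy atom of the heater's side chain within
  4.5 Å of a heavy atom of a residue at least three apart in sequence. Rate
  `D_C / r^p` with `r` the minimum heavy-atom distance. A residue pair can
  carry both an HB and an HC edge. Heater contacts matter despite the
  general inefficiency of non-polar contacts because of the large energy
  the heater carries.

The functional form `D/r^p` (default `p = 2`) makes the stated
proportionality to the two transport coefficients explicit and keeps units
transparent (`D` in Å²/ps); the exponent is configurable. Two one-way
channels complete the open system: a HEAT edge injecting the photo-deposited
quantum from a heater pool into the donor residue at rate `k_h`, and COOL
edges draining every residue into a solvent sink at rate `k_s`.

The heater's initial condition corresponds to an instantaneous temperature
jump: with an electronic excitation energy of ≈2 eV spread over 39 heater
degrees of freedom, ΔT = E_exc/(k_B·n_dof) ≈ 595 K. Trajectories are
propagated in normalized units (heater quantum = 1); the ΔT conversion is
available through `HeaterSpec`.

### Numerical propagation

The system is propagated exactly with matrix exponentials: one
`expm(K·dt)` per distinct step length, then matrix–vector products. For the
network sizes here (≲ 60 states including the flag expansion) this is both
faster and better-conditioned than an adaptive ODE stepper, handles the
stiff `k_h`/`k_s` ratio exactly, and makes grid-independence testable: the
solution at a shared time is identical (to roundoff) for any grid that
reaches it. Total energy over all nodes including the sink is conserved to
~1e-15 relative. Peak times are refined by a parabola through the discrete
maximum and its neighbours, ties broken toward earlier times; boundary
maxima (monotone decay) report the boundary time.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `D_B` | 57.8 | Å²/ps | adjacent-residue backbone transfer in 0.2–0.3 ps at d = 3.8 Å |
| `D_C` | 1.7 | Å²/ps | contact transfer times of a few ps at r ≈ 2.9 Å |
| `k_h` | 1.0 | 1/ps | ~1 ps internal-conversion release of the heater energy |
| `k_s` | 1/6 | 1/ps | experimental solvent dissipation time of 6 ps, used as input |
| `Q` | 1 (3.1 when corrected) | — | global fit to experimental peak times |
| `hb_cutoff` / `hb_angle_min` | 3.5 Å / 120° | | standard backbone H-bond criteria |
| `hc_cutoff` | 4.5 Å | | heavy-atom van-der-Waals contact range |

The quantum correction multiplies `D_B`, `D_C` and `k_h` but not `k_s`:
solvent dissipation is slow compared to an intramolecular step and little
affected by quantum fluctuations, and its experimental value is taken as
input. Applying the correction commutes with network assembly (tested
edge-by-edge).

## Pathway decomposition

The master equation's linearity lets energy be read as independent quanta
performing a continuous-time Markov jump process with the same rates. A
quantum's pathway is its edge-class sequence up to **first passage** at the
sensor; later recrossings are not counted — the decomposition answers
"which route did arriving energy take", matching a cumulative-arrival
reading of the sensor signal. An occupation-weighted alternative would
additionally weight residence time and is not implemented. Mixed paths are
classified with precedence HC > HB > BB (HC edges emanate from the heater
and are traversed first when present).

Two independent routes compute the class-resolved arrival fractions:

1. **Exact**: the state space is expanded to (node, seen-HB, seen-HC), the
   sensor split into four absorbing states by flag combination, and the
   expanded linear system integrated. The flag expansion provably leaves the
   total first-passage probability unchanged (tested against the unexpanded
   absorbing chain to 1e-9).
2. **Monte Carlo**: vectorized jump-chain sampling (exponential waiting
   times, branch probabilities ∝ rates), each walker terminating at first
   sensor arrival, solvent absorption, or the 50 ps horizon. One walker
   carries one quantum, which linearity makes an unbiased sampler of the
   flow.

The two must agree within binomial noise; tests enforce 3σ agreement at
10⁶ walkers on all fixtures, and a brute-force path enumeration over the
embedded discrete chain serves as a third, independent oracle on small
toys. Default walker counts (10⁶ in analyses, 3·10⁵ in the summary script)
put class-share standard errors well below one percentage point; larger
counts are a config knob away.

A caveat found while testing: removing a *single* contact does not
necessarily delay the sensor peak. Contacts that divert flux away from the
sensor (e.g. mid-hairpin H-bonds when the donor–sensor pair sits at the
termini) slightly advance it when cut. Monotone delay holds for contacts
incident to the donor or sensor, and for pruning all contacts at once —
which is what the denaturant emulation (`prune_contacts`) represents.

## Calibration

* **Transport coefficients** `(D_B, D_C, k_h)` are fitted to
  ensemble-averaged residue-energy traces by minimizing summed squared
  residuals over all residues and times, in log-parameter space with a
  coarse pre-scan followed by Nelder–Mead (bounds `D ≤ 10³ Å²/ps`,
  `k_h ≤ 10² ps⁻¹` enforced by rejection). `k_s` stays fixed at its
  experimental value. Noise-free synthetic data is recovered to <1%; at the
  5000-trajectory noise level the median error over 20 seeds stays <10%.
* **Quantum correction**: a single `Q ∈ [1, 10]` scaling all variants'
  intramolecular and heater rates identically, minimizing the summed squared
  difference between modelled and experimental sensor **peak times** (not
  full transients) with equal variant weights. The objective is profiled on
  a scan grid (unimodality is checked and flagged) and refined by bounded
  scalar minimization. A synthetic experiment generated at `Q* = 3.1` is
  recovered within 2%.
* **Cooling rate**: log-linear least squares on the strictly positive
  post-peak tail of a transient; reported as `k_s` and dissipation time
  `1/k_s`.

## Transient-IR forward model

The sensor's azide stretch band (Gaussian, centre 2120 cm⁻¹, width
σ = 10 cm⁻¹ by default; the band shape is a modelling choice) red-shifts by
`c_ν·E(t)` with the sensor's excess energy. The difference spectrum
`ΔA(ν, t) = band(ν; shifted) − band(ν; 0)` on 32 detector pixels shows
induced absorption on the low-wavenumber side and bleach on the high side;
in the small-shift regime (`c_ν·E ≪ σ`) its summed absolute value is
proportional to the shift, hence to the sensor energy, so the scalar VET
transient `Σ|ΔA|` peaks when the sensor energy peaks (tested to within one
delay step, and against an analytically solvable heater–residue–solvent
chain whose peak time is `ln(k_h/k_s)/(k_h−k_s) = 2.150 ps`). Signal pixels
are selected automatically as those whose time-averaged noise-free `|ΔA|`
exceeds 10% of the maximum. Pump-scatter, cross-phase modulation and
polarization effects are not modelled.

## Synthetic data

The generator emulates the study's inputs without downloads or MD engines:

* **Idealized hairpin**: a deterministic antiparallel two-strand scaffold,
  Cα spacing 3.8 Å along strands, residue `i` registered with `n+1−i`
  across a 5.6 Å strand gap so every registered pair forms reciprocal
  backbone H-bonds at N···O ≈ 2.8 Å. The donor carries dummy side-chain
  heavy atoms reaching van-der-Waals range (~3.1–3.6 Å) of the opposing
  strand so heater contacts are detectable. It reproduces the fold's
  topology (registered H-bond ladder, terminal donor–sensor contact) but
  not side-chain packing, turn geometry, or conformational heterogeneity —
  passing tests demonstrate correctness of the transport analysis on this
  topology, not force-field realism.
* **Variants**: V1 = (donor 1, sensor 12, opposite strands) and
  V4 = (1, 5, same strand) are fixed by the design; V2 = (1, 10) and
  V3 = (2, 9) are assumptions chosen as opposite-strand pairs with backbone
  separations between V1's and V4's.
* **Ensembles**: the ensemble mean over `n_traj` (default 5000)
  non-equilibrium trajectories of 50 ps is emulated as the exact
  master-equation solution plus i.i.d. Gaussian noise with
  σ = E_scale/√n_traj — the central-limit behaviour of an average of
  independent trajectories. Real MD noise is correlated in time and across
  residues; the i.i.d. model is the simplest member of the correct scaling
  family and is what the recovery guarantees are stated against.

## Problem sizes and reproducibility

Analyses use a 0–50 ps grid at 0.05 ps (fits at 0.1 ps), 12-residue
networks (≤ 60 expanded states), 10⁶ Monte Carlo walkers in the acceptance
checks and 3·10⁵ per variant in the summary script — sizes at which the
exact propagator and the vectorized sampler run in seconds. Every stochastic
stage (ensemble noise, pruning selection, walkers) draws from a
`numpy` `SeedSequence` fanned out from one global seed, so identical
configurations reproduce outputs bit-identically.

## Known limitations

* Rates are structure-derived through two coefficients; no per-contact
  chemistry (salt bridges vs H-bonds vs stacking) beyond the HB/HC split.
* First-passage pathway accounting ignores energy that reaches the sensor,
  leaves, and returns.
* The idealized scaffold's contact distances are canonical, not
  conformationally averaged; absolute peak times and class percentages on it
  are illustrative, while orderings (opposite- vs same-strand, intact vs
  pruned, classical vs quantum-corrected) are the robust observables.
* Partial unfolding is represented purely as contact pruning; denaturant
  thermodynamics and ensemble heterogeneity are not modelled.
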