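# Methods

This document records the model equations as implemented, every parameter
with its units, default and rationale, the numerical choices, and the known
limitations. All statements about model behavior below are computed by the
test suite (`tests/`) or by `scripts/acceptance.py`.

## 1. Habitat

A chemostat of unit volume (1 ml), so densities and counts coincide. Medium
with the limiting resource at concentration `A` flows in at dilution rate
`w`; cells, phage and unused resource wash out at the same rate. Growth is
Monod: `ψᵢ(R) = Vᵢ·R/(k + R)`. Resource dynamics:

    dR/dt = w·(A − R) − e·Σᵢ ψᵢ(R)·Xᵢ

| symbol | meaning | units | default |
|---|---|---|---|
| `A` | reservoir resource concentration | µg/ml | 50 |
| `w` | dilution (washout) rate | hr⁻¹ | 0.2 |
| `k` | Monod half-saturation constant | µg/ml | 0.25 |
| `e` | conversion efficiency (resource per new cell) | µg | 5×10⁻⁷ |

These four are shared by every scenario preset. They give a single-species
carrying capacity `N* = (A − R*)/e = 9.9875×10⁷ ≈ 10⁸ cells/ml` with
`R* = kw/(V − w) = 0.0625 µg/ml` at `V = 1` (verified to 10⁻⁶ relative
against simulation in `tests/test_core.py` and to 0.5% over 50 random draws
of `V` in `tests/test_acceptance.py`).

## 2. Phage model

States `N` (sensitive non-CRISPR), `N_R` (envelope-resistant), `C` (sensitive
CRISPR), `C_R` (immune CRISPR), `P` (free phage), `R`. With
`ψᵢ = monod_growth(Vᵢ, k, R)`, the MOI `M = P/max(C_R, 1)`, the
MOI-dependent killing rate

    δ(M) = δ_MIN + x·(δ_MAX − δ_MIN)·Mⁿ/(qⁿ + Mⁿ),

and `[H] = max(H − refuge, 0)` the host density exposed to adsorption
(section 5):

    dN/dt   = ψ_N·N − μ·ψ_N·N − δ_N·[N]·P − w·N
    dN_R/dt = ψ_NR·N_R + μ·ψ_N·N − w·N_R
    dC/dt   = ψ_C·C − δ_C·[C]·P + v·C_R − w·C
    dC_R/dt = ψ_CR·C_R + m·δ_C·[C]·P − δ(M)·[C_R]·P − v·C_R − w·C_R
    dP/dt   = β_N·δ_N·[N]·P + β_C·(1−m)·δ_C·[C]·P − m·δ_C·[C]·P
              + β_CR·δ(M)·[C_R]·P − δ_MAX·[C_R]·P − w·P

Interpretation: phage adsorb to `N` and `C` by mass action; a fraction `m` of
infections of `C` abort and immunize the cell (consuming the adsorbed phage,
hence the `−m·δ_C·[C]·P` term), the rest burst; immune `C_R` cells soak up
phage at the maximum rate `δ_MAX` (the `−δ_MAX·[C_R]·P` sink) but are
actually killed — and produce phage — only at the MOI-dependent rate `δ(M)`,
which rises from `δ_MIN` (effective immunity) toward
`δ_MIN + x·(δ_MAX − δ_MIN)` when immune cells are saturated with phage.
Phage loss to productive infections of `N` and `C` is subsumed in the burst
sizes.

| symbol | meaning | units | default | why |
|---|---|---|---|---|
| `V_N, V_NR, V_C, V_CR` | max growth rates | hr⁻¹ | 1.0, 0.85, 0.95, 0.90 | scenario-defining costs of resistance/CRISPR carriage |
| `delta_N, delta_C` | adsorption rate constants | ml/hr per phage–cell pair | 5×10⁻⁹ | typical coliphage adsorption scale |
| `delta_MIN, delta_MAX` | bounds of δ(M) | same | 10⁻¹⁴, 5×10⁻⁹ | near-perfect immunity floor; max = plain adsorption |
| `x` | MOI-effect magnitude ∈ [0,1] | — | 0 | scenario-defining (0, 0.2, 0.5 across presets) |
| `q`, `n` | half-effect MOI, Hill exponent | — | 10², 2 | sigmoid saturation of immune overwhelm |
| `beta_N, beta_C, beta_CR` | burst sizes | phage/cell | 80 | realistic for E. coli T-phages; not fixed by any preset's defining values, so chosen once and surfaced in every config echo |
| `mu` | mutation rate N→N_R | per division | 10⁻⁸ | typical per-division rate; growth-coupled flux `μ·ψ_N·N` (flag `mutation_growth_coupled` switches to per-hour) |
| `m` | abortive-infection probability | — | 0.1 | plausible mid-range; configurable, logged in every echo |
| `v` | immunity-loss rate C_R→C | hr⁻¹ | 10⁻³ | constant per-hour rate (not growth-coupled) |

## 3. Plasmid model

States `N`, `N_P`, `C`, `C_P`, `C_X` (plasmid-immune CRISPR), `R`. With
transfer fluxes `T_N = (γ_NN·N_P + γ_CN·C_P)·N` and
`T_C = (γ_NC·N_P + γ_CC·C_P)·C`:

    dN/dt   = ψ_N·N − T_N + τ_N·N_P + z·C − w·N
    dN_P/dt = ψ_NP·N_P + T_N − τ_N·N_P + z·C_P − w·N_P
    dC/dt   = ψ_C·C − T_C + τ_C·C_P + v·C_X − z·C − w·C
    dC_P/dt = ψ_CP·C_P + (1−m)·T_C − τ_C·C_P − z·C_P − w·C_P
    dC_X/dt = ψ_X·C_X + m·T_C − v·C_X − w·C_X

Conjugation is mass action in donor × recipient; segregation returns
plasmid-bearing cells to the plasmid-free state at per-hour rates `τ`; a
fraction `m` of transfers into `C` immunize the recipient directly
(`C → C_X`); `z` is loss of the CRISPR element (`C → N`, `C_P → N_P`). `C_X`
carries no complete plasmid and donates nothing; by default it does not lose
the CRISPR element (flag `z_on_CX` extends `z` to `C_X → N`). Segregation is
per-hour, not per-division: this is the convention under which the printed
critical transfer rate 1.1×10⁻¹⁰ (section 4) is exact.

| symbol | meaning | units | default |
|---|---|---|---|
| `V_N, V_NP, V_C, V_CP, V_X` | max growth rates | hr⁻¹ | 1.0, 0.95, 0.97, 0.88, 0.96 |
| `gamma_NN, gamma_NC, gamma_CN, gamma_CC` | transfer rate constants | ml·cell⁻¹·hr⁻¹ | 10⁻⁹ |
| `tau_N, tau_C` | segregation rates | hr⁻¹ | 10⁻³ |
| `m` | immunization probability on transfer into C | — | 0.2 |
| `v` | immunity-loss rate C_X→C | hr⁻¹ | 10⁻³ |
| `z` | CRISPR-element loss rate | hr⁻¹ | 10⁻⁸ |

With `m = 0` and `z = 0` conjugation only relabels cells within each lineage;
the transfer terms cancel exactly across donor/recipient equations
(`tests/test_plasmid.py::test_transfer_conserves_cells`).

## 4. Analytic criteria

* **Resource equilibrium** `R* = kw/(V − w)` (requires `V > w`, else washout).
* **Carrying capacity** `N* = (A − R*)/e`.
* **Phage establishment**: production must beat washout at the resident
  equilibrium, `δ_N·β_N·N* > w`; critical product `w/N*`. At the stated
  resident density 10⁸ cells/ml this is 2×10⁻⁹ ml/hr; simulation brackets at
  0.5×/2× confirm decline/establishment of a 10³/ml inoculum over 50 hr.
* **Plasmid maintenance**: at the resident equilibrium the plasmid-free
  strain grows at exactly `w`, so the plasmid-bearing strain runs a deficit
  `w·(1 − V_NP/V_N)`; transfer must cover that deficit plus segregation:
  `γ_NN·N* > w·(1 − V_NP/V_N) + τ_N`. For `V_N = 1`, `V_NP = 0.95`,
  `w = 0.2`, `τ_N = 10⁻³`, `N* = 10⁸`: critical `γ_NN = 1.1×10⁻¹⁰`.
  Simulation brackets at `γ = 10⁻⁹` (ascends to dominance) and `10⁻¹¹`
  (lost) confirm it.
* **Bacteria–phage coexistence** (two-species pair): `N* = w/(β·δ)`, `R*` the
  positive root of `w(A − R)(k + R) = e·V·N*·R`, `P* = (ψ(R*) − w)/δ`. Used
  to start invasion presets at the resident community's fixed point.
* **Immune-culture phage decline** (batch, no washout): with immune cells
  growing as `C_R0·e^{V_R t}` and adsorbing at `δ_MAX`,
  `P(t) = P0·exp(−δ_MAX·C_R0·(e^{V_R t} − 1)/V_R)` (limit
  `P0·exp(−δ_MAX·C_R0·t)` at `V_R = 0`); verified against direct quadrature
  of its defining ODE to 10⁻⁶ relative.

## 5. Numerical choices

* **Integrator**: `scipy.integrate.ode` with `lsoda` (stiff-capable,
  default) or `dopri5` (explicit Runge–Kutta); `rtol = 10⁻⁸`,
  `atol = 10⁻¹⁰`; states reported every 0.5 hr. Halving the tolerances
  changes final states of the oscillatory fig4a preset by < 0.1% relative,
  and the two solver modes agree to < 0.5% (tested).
* **Nonnegativity**: the solver runs on raw densities; reported states are
  floored at zero. No log transform, so the extinction event semantics stay
  exact.
* **Phage extinction event**: when total phage density drops below
  10⁻¹ particles/ml at a reported step, phage are set to exactly zero, the
  event is logged, and the solver restarts. Applied at reported steps only.
* **Refuge**: each host population has a low-density refuge
  (default 10² cells/ml) that bounds the predator–prey oscillations.
  Implemented as adsorption on the *excess* density above the refuge,
  `[H] = max(H − refuge, 0)`, rather than an on/off switch at the boundary:
  a hard switch creates a chattering sliding mode when predation pins a host
  exactly at the refuge density, on which both solvers stall; the excess
  form is continuous, still gives exactly zero adsorption below the refuge,
  and differs negligibly (≤ refuge/H relative) above it.
* **MOI guard**: `M = P/max(C_R, 1 cell/ml)`, so `M` stays finite and the
  killing term vanishes smoothly as `C_R → 0`.
* **Initial conditions** (invasion presets): residents at their analytic
  equilibrium — the single-species equilibrium for bacteria-only residents,
  the two-species coexistence fixed point when a resident phage is present
  (starting instead from the phage-free equilibrium plus a phage inoculum
  gives a violent transient with P spiking to ~7×10⁹/ml but the same end
  regimes); invaders at 10³ cells/ml; phage inocula at 10⁴/ml. The fig6c
  preset first equilibrates the N/N_P pair by a 1500-hr burn-in, then
  introduces `C_X`.
* **Horizons**: 500 hr (phage presets), 2000 hr (plasmid presets; the
  immune-plasmid invasion of fig6c is deliberately slow).
* **Outcome classification**: means over the final 20% of the run (robust to
  persistent oscillations); persistence floor 1 cell/ml; phage-limited ⇔
  mean `R` > 0.5·A; washout if no bacterial population persists.
* **Determinism**: no randomness anywhere in the models; preset runs are
  bit-reproducible for fixed solver settings (tested).

Problem sizes are small: 6 ODE states, ≤ 4000 reported steps; every preset
runs in well under a second on one CPU.

## 6. Known limitations

* **fig4c (strong MOI effect, x = 0.5) does not reach a phage-limited
  state** under the documented defaults (`m = 0.1`, `v = 10⁻³`, `β = 80`).
  The candidate phage-limited state in which `C_R` is held down by the
  MOI-override requires a standing phage density
  `P ≥ (ψ_CR − w − v)/(x·δ_MAX) ≈ 2.8×10⁸/ml`, more than the
  N-supported maximum `(ψ_N(R≈A) − w)/δ_N ≈ 1.6×10⁸/ml`; the state must be
  C_R-self-sustained and is oscillatorily unstable (started exactly there,
  `C_R` escapes through a phage trough once `M < q`). Scans over
  `β ∈ [20, 300]` and `m ∈ [0.01, 0.3]` always end resource-limited with
  `C_R` dominant, as in fig4b/fig4d. The corresponding acceptance test is
  left failing rather than re-tuned.
* **fig5a (modest resistance cost) does not produce the
  resistance-sweep → phage-extinction → N-recovery sequence** under the same
  defaults: with `m = 0.1` the invasion transient builds `C_R` to > 10⁷/ml,
  and the immunity-loss backflow `v·C_R` continuously replenishes
  phage-sensitive `C`, keeping the phage fed (`P ≈ 10⁷/ml` persists).
  Scanning `m ∈ {0.01, 0.03, 0.1, 0.3}` gives `C_R` dominance throughout;
  the sequence would require `m ≲ 10⁻³` or a much smaller `v`. The defaults
  were not moved; the acceptance test is left failing.
* **fig6b**: `C_X` dominance with `N`, `N_P` minorities verifies, but `C`
  does not decline to extinction: the backflow `v·C_X ≈ 7×10⁴ cells/ml/hr`
  maintains `C` at ~2×10⁷/ml indefinitely (the balance
  inflow / per-capita deficit reproduces the simulated level). A smaller `v`
  would let `C` and `C_P` be lost.
* No spatial structure, latent periods, stochastic demography, multiple
  phage species, host-range evolution, or antibiotic-pulse selection.
* The MOI override acts through the instantaneous ratio `P/C_R` only; no
  memory of past exposure.
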