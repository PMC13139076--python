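# Methods

This note documents the model, the numerical choices and the defaults of
the `zonetox` pipeline — in particular which constants are anchored to
published tables and which are this package's own configuration choices.

## Scope and assumptions

The pipeline estimates the spatial pattern of hepatocellular necrosis in
a liver lobule after a single oral APAP overdose. Its core assumptions:

* **Linear mass-action kinetics.** All metabolic steps are first or
  second order; no Michaelis–Menten saturation. This is adequate for
  studying *relative* zonation effects but overstates clearance at the
  highest doses (sulfation does saturate dynamically, because its PAPS
  co-substrate depletes).
* **One-way coupling.** Blood delivers drug to cells; cellular uptake
  feeds back on the transport field only through a lumped first-order
  loss term, not per-cell. Cells are therefore independent given their
  exposure rows, which is what makes whole-lobule batching trivial.
* **Injury is adduct-driven.** The NAPQI–Cys adduct load C drives the
  healthy fraction H into a damaged pool Z and on to lysis L;
  regeneration converts lysed capacity back at a slow logistic rate.
  dH + dZ + dL = 0 term by term, so H+Z+L = 1 is an exact invariant used
  as an integrator check.

## Parameters

### Anchored to published tables

Baseline (non-zonated) rate constants: `ku, kS, kG, kCYP1A2, kCYP2E1,
kCYP3A4, kGSH, kPSH, G0, bG`. The published endpoint table prints three
significant figures; four baselines are stored at one extra digit
(`ku = 8.333333e-5`, `kS = 2.615e9`, `kGSH = 1.852e13`,
`kPSH = 1.274e-3`) because the printed endpoints of their rows are
roundings of a higher-precision constant — each working value is chosen
inside the interval consistent with *all eight* printed cells of its row
and reproduces the printed 0 % value exactly. The glucuronidation
baseline is 3.46e-5 (the portal 0 % entry); the central 0 % entry of
that row is inconsistent with every nonzero-level cell and is treated as
a typographical error.

### Configuration defaults (no published values)

No supplementary constant table was available; the following are this
package's own defaults, chosen for dimensional consistency with the
anchored constants and documented magnitude reasoning:

| name | value | rationale |
|---|---|---|
| `kN` | 1e-4 /s | minor reverse-oxidation return flux |
| `bS, dS, S0` | 1e-19, 2e-5, 5e-15 | PAPS pool at steady state `S0=bS/dS`; gives sulfation ~25 % of clearance at low dose, matching the dominant-conjugation picture |
| `dG` | `bG/G0` ≈ 2.31e-5 /s | steady-start consistency `G0 = bG/dG` |
| `dC` | 1e-4 /s | adduct clearance half-life ~2 h |
| `r` | 2e-6 /s | regeneration over ~days |
| `eta` | 8e9 /(mol·s) | see injury-regime placement below |
| `deltaZ` | 1e-4 /s | damaged→lysed over hours |
| PBPK flows/volumes | hepatic artery 6.5e-3 L/s, portal 1.75e-2 L/s, liver 1.8 L, systemic 42 L, `ka` 5e-4 /s, `kelim` 4e-5 /s, `khep` 2e-4 /s | literature-typical human magnitudes; effective APAP half-life ~4 h at overdose |
| transport | transit 60 s, dispersion 0.2, uptake loss 0.035 /s | see below |
| `exposure_scale` | 1.5e-8 L·s | lumped sinusoid-volume × residence-time conversion; see below |
| thresholds | L ≥ 0.5 necrosed, Z ≥ 0.25 damaged, R ≥ 0.05 regenerated | a fully lysed cell is always necrosed; rule order L, Z, R |

With the GSH pool full, NAPQI conjugation outpaces adduct formation
(`kGSH·G0 ≈ 0.13 /s` vs `kPSH ≈ 1.3e-3 /s`); injury requires GSH
depletion, i.e. a sustained NAPQI production flux above the replacement
rate `bG`. That switch is the model's central nonlinearity.

### Injury-regime placement

`exposure_scale` and `eta` position the four clinical overdoses on the
GSH-depletion switch. They were fixed once, before the test suite was
written, so that (i) the lowest overdose (6.1 g) sits just above the
depletion threshold — a small periportal necrotic band, matching the
clinical picture of ~6 g as a borderline-toxic adult dose — and (ii) the
highest overdose (27.1 g) injures most of the lobule, so all three zones
carry baseline necrosis and zone-ratio statistics are well defined.
Absolute necrosed counts reported alongside the endpoint tables are
*not* calibration targets: they depend on a fully resolved blood-flow
exposure field and a complete constant set that no surrogate can
replicate, and the package treats them as qualitative characterization
only.

## The transport surrogate and what it does not emulate

A fully resolved exposure stage would be a transient 3-D
hexagonal-lobule CFD simulation of sinusoidal blood flow. Here it is
reduced to a 1-D signal transform: delay `x·T`, Gaussian
dispersion of width `dispersion·x·T`, attenuation `exp(-λ·x·T)` with
`λ·T = 2.1` (peak exposure spans a factor ≈ 8 across the lobule,
comparable to the 4.4× dose span of the studied patients). The operator
is linear and strictly monotone in x. Consequences:

* Baseline (non-zonated) necrosis forms a **periportal band** whose
  frontier moves centrally with dose — a deterministic, monotone
  exposure field cannot reproduce the roughly zone-uniform baseline
  necrosis a CFD field with path-to-path variability produces.
  Zonation-driven *shifts* of the pattern (the quantity under study) are
  unaffected: uptake/CYP/GSH-supply gradients move necrosis
  pericentrally, the glucuronidation gradient periportally.
* Passing tests therefore validate directional and distributional
  claims, not absolute spatial patterns of real lobules.

The synthetic cohort generator samples doses and horizons uniformly in a
configured range with a seeded generator; it emulates the *spread* of an
overdose cohort, not its empirical joint distribution (no dose–delay
correlation, no demographics).

## Zonation gradients

Linear hypotheses: value at the favored end `baseline·(1+level)`,
opposite end `baseline·(1-level)`, linear in the rank coordinate;
uniform rank spacing makes the lattice mean exactly the baseline.
Level ≥ 1 is rejected (negative rates). H5 varies GSH production `bG`
with a single multiplier and recomputes `G0 = bG/dG` per cell (dG held
fixed), keeping every cell at its production/degradation steady state.

CYP isoenzymes (H4): endpoints are tabulated measured activities, not
`baseline·(1±level)`; they are taken verbatim. The profile between the
pins is a normalized logistic ramp (width 0.08 in x) whose midpoint is
solved by `brentq` so the lattice mean equals the baseline to ≤ 1e-6
relative. If the requested width cannot reach the target mean (coarse
lattices bound the attainable mean by the pinned end values) the ramp is
sharpened stepwise down to width 0.012 before declaring the profile
infeasible. On very small lattices (< ~8 cells) some 80 % profiles are
genuinely infeasible; simulation lattices in this repository use ≥ 12
cells.

Three-significant-figure table values are rounded half-away-from-zero on
the shortest decimal representation, matching the printed style
(3.435e-15 → 3.44e-15).

## Numerics

* **PBPK**: closed linear system propagated by `expm(A·dt)`; mass
  conservation to machine precision, grid 300 s.
* **Single cell**: SciPy `solve_ivp` Radau (implicit Runge–Kutta, stiff),
  default `rtol 1e-6`. The absolute tolerance defaults to a per-component
  vector (1e-21 for the molar pools, 1e-12 for the H/Z/L/R fractions): a
  scalar atol of 1e-12 would sit *above* the ~1e-15 mol pool scales and
  void error control on the chemistry.
* **Whole lobule**: fixed-step RK4 kernel (numba) at `dt = 5 s`, outputs
  every 1,800 s. The fastest system rate is `kGSH·G ≈ 0.13 /s`
  (≈ 0.23 /s under 80 % zonation), so `λ·dt ≤ 1.2` — inside the RK4
  stability region with headroom. The kernel is cross-validated against
  the Radau path on real forcings to ~1e-4 relative in the tests. RK4
  preserves the linear invariant H+Z+L exactly.
* **Problem sizes**: analysis grid and acceptance runs use a 240-cell
  lobule (zones 80/80/80); simulation-heavy tests use 60 cells. The
  necrosis frontier is a smooth function of the rank coordinate, so zone
  tallies scale with lattice size; 240 cells resolve the frontier to
  < 0.5 % of the axis. Full-size (5,114-cell) runs use the same code
  path and memory (< 100 MB per run) and simply take proportionally
  longer.
* **Tie-breaks**: the time of maximum necrosis takes the *earliest*
  maximum (`argmax` semantics); classification rule order is
  necrosed → damaged → regenerated → healthy.
* **Degenerate inputs**: zero dose yields identically zero series and no
  necrosis; chi-square tables drop all-zero columns before testing, and
  identical or single-column tables report statistic 0 / p 1 (a blank
  star cell) rather than an error.

## Statistical report

Overall mode tables are 2 × {healthy, necrotic, regenerated}; cells that
are damaged but neither lysed nor regenerated count with the healthy
(viable, non-necrosed) column — the discrete "damaged" label exists in
the simulation output but the published report structure carries three
categories. Zonal mode is 2 × {necrosed, not} within the pericentral
zone by default; a zone-1-vs-zone-3 contrast within the zonated run is
available (`zonal_contrast="zone"`). Both constructions are consistent
readings of a "necrosed-cell comparison"; the choice is recorded per
report, with statistic, dof, p and raw counts stored so every star is
auditable. No continuity correction, no multiple-testing adjustment
(raw per-test stars), both available as flags.

## Known limitations

* Linear kinetics overstate phase-II clearance at extreme doses.
* The 1-D exposure surrogate cannot produce zone-uniform baseline
  injury (see above); absolute necrosed counts are not comparable to
  CFD-coupled results.
* Classification thresholds are modeling choices; tallies at t* depend
  on them smoothly but not negligibly.
* Single-hypothesis zonation only; joint gradients are out of scope.
* No inflammation, senescence, antidote (NAC) kinetics, or biomarker
  (ALT/AST/INR) output.
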