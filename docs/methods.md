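# Model and methods

## The model

**Myocyte.** The ventricular cell is the ten Tusscher–Noble–Noble–Panfilov
(2004) human epicardial model: twelve membrane currents (I_Na, I_CaL, I_to,
I_Ks, I_Kr, I_K1, I_NaCa, I_NaK, I_pCa, I_pK, I_bNa, I_bCa), ten
voltage-dependent gates, two calcium-dependent gates (f_Ca and the SR
release gate g), and four ion pools (Na_i, K_i, Ca_i, Ca_SR).  Membrane
dynamics are

    dV_m/dt = −(I_ion + I_stim + I_coupling/C_m),

with current densities in pA/pF.  All constants live on `MyocyteParams`
and are overridable; the total cellular capacitance C_m = 185 pF (the
value implied by the model's volume/capacitance bookkeeping) converts
absolute junctional currents (pA) to densities.  Depolarizing stimuli are
*negative* in this sign convention; the single-cell standard is
−52 pA/pF for 3 ms at t = 50 ms.

**Fibroblast.** A passive RC element:

    C_f dV_f/dt = −G_f (V_f − E_f) + I_in,

with defaults C_f = 6.3 pF, G_f = 4 nS, E_f = −49 mV (culture-scale
values; E_f is restricted to [−100, 20] mV).  Uncoupled, V_f relaxes to
E_f with time constant C_f/G_f.

**MF composite.** A myocyte joined to N_f identical fibroblasts through
per-junction conductance g_j.  Because identical fibroblasts share one
membrane potential, the composite is integrated with a single *lumped*
fibroblast (N_f C_f, N_f G_f) coupled at G_gap = N_f g_j — an exact
reduction (the lumped ODE divides through to the per-fibroblast one).
Note that this is *not* the same as attaching one unit fibroblast at
N_f g_j: the effective diastolic load is N_f · series(g_j, G_f), so the
composite's response grows with N_f at fixed g_j.  Depending on (E_f,
G_gap, N_f) the composite is excitable, autorhythmic (spontaneous slow
upstrokes, ~1 mV/ms at threshold — the regime classifier therefore uses a
0.5 mV/ms slope bound rather than the 5 mV/ms used for propagated beats)
or oscillatory.

**Bilayer tissue.** A 2D myocyte monodomain (forward Euler, 5-point
Laplacian, D = 0.00154 cm²/ms, dx = 0.225 mm, dt = 0.02 ms) with a
registered fibroblast layer:

* *zero-sided* — each fibroblast couples only to its local myocyte
  (on-site G_gap);
* *one-sided* — fibroblast–fibroblast neighbor conductances G_ff as well;
* *two-sided* — additionally each myocyte exchanges current with its four
  nearest fibroblast nodes through a pairwise conductance.  The two
  cross-conductance parameters G_mf and G_fm describe the same physical
  junctions and must be equal, otherwise the two ends of a junction would
  see different currents and charge would not be conserved.

Boundaries are no-flux via edge-replicated ghost nodes; this choice (rather
than mirror-across-node ghosts) makes every pairwise conductance term
cancel exactly at the border, so the junctional exchange sums to zero over
the grid to machine precision.  Node (i, j) sits at (x, y) =
(j·dx, i·dx).

## Numerics

Voltages and ion pools advance by forward Euler at dt = 0.02 ms.  The ten
voltage gates use the exponential (Rush–Larsen) update by default: the
fast-Na activation gate has τ_m ≈ 10⁻³ ms near rest, so a pure
forward-Euler gate update is unconditionally unstable at any practical dt;
a forward-Euler gate mode exists behind a flag for experimentation.  The
f_Ca and g gates (τ = 2 ms) use forward Euler with the standard
conditional lock (no increase while V > −60 mV).

The tissue kernel tabulates every purely voltage-dependent factor (gate
steady states and update factors, the I_CaL Goldman-type prefactors, the
Na/Ca-exchanger and Na/K-pump voltage factors, the inward-rectifier factor
on V − E_K) on a 0.05 mV grid with linear interpolation, and refreshes the
four Nernst potentials from the ion pools every 8 steps (0.16 ms); the
pools drift on second timescales, so the interim error is below the
interpolation error.  The single-cell path evaluates everything exactly —
the two paths agree bitwise in the decoupled-limit consistency tests that
compare tissue runs against each other, and to well below measurement
tolerances against the exact path.

Explicit-Euler stability (dt ≤ dx²/4D) is checked before stepping.  Tissue
runs abort on numerical blow-up (|V| > 10⁴ mV or NaN) with the offending
node and time; single-cell runs abort at |V_m| > 200 mV.  Everything is
deterministic: fixed row-major traversal, no randomness anywhere.

## Measurement conventions

* **Upstroke** — the instant of maximal dV/dt (forward difference).  For
  stimulated beats the search is pinned to a 20 ms window after stimulus
  onset so spontaneous activity elsewhere in the trace cannot hijack it.
* **APD levels** — by default the x% level is the absolute voltage
  (x/100)·V_rest of the *control* AP, i.e. repolarization measured as the
  fractional return from 0 mV to rest, and the same absolute levels are
  applied to the coupled beat in paired comparisons.  This zero-baseline
  convention is the one under which the composite delta table reproduces
  the reference values; the common amplitude convention
  V_max − x%(V_max − V_rest) is available via `level_mode="amplitude"`.
* **V_rest** — the post-AP diastolic minimum, read from late diastole
  (≥ 550 ms after the upstroke, or the final quarter of a short diastole)
  so the brief post-repolarization undershoot does not bias it.  The
  pre-upstroke value is also reported.
* **CV** — two probes at 25% and 75% of the domain length on the midline;
  activation = upward crossing of −40 mV (sub-step interpolation).
  Failure covers both a front that never arrives and crossings implying
  an implausible velocity (outside 3–200 cm/s — a tonically depolarizing
  substrate crosses the threshold near-simultaneously everywhere).
* **Beats and spectra** — upstrokes are −40 mV upward crossings with
  dV/dt > 5 mV/ms; the spectrum is the plain (unwindowed) periodogram of
  the mean-removed series, resolution 1/(N·Δt).
* **Tip tracking** — the I_Na snapshot channel stores the *peak* |I_Na| at
  each node since the previous frame: the regenerative sodium surge lasts
  well under a millisecond, so an instantaneous field is aliased at any
  practical cadence, while the swept-peak field paints the front's path as
  a connected band.  The tip is the interior free end of that band:
  threshold mask → morphological closing → speckle removal →
  skeletonization → endpoints with one skeleton neighbor, excluding
  endpoints near the border, endpoints whose forward direction still
  contains mask (the medial axis of a wide band ends inside the band), and
  near-duplicates; sub-node refinement by a local |I_Na|-weighted
  centroid.  The reference threshold is 0.25× the peak |I_Na| of the
  weakest just-suprathreshold single-cell AP (bisected to 1%): fronts
  re-entering partially recovered tissue peak at roughly half the fully
  recovered surge, and the quarter keeps the band connected while
  excluding sub-regenerative activity.  A cross-check tracker intersects
  the V = −35 mV isoline with the frame-difference (dV/dt = 0) contour;
  with 8 ms frames it localizes the nearly stationary core *center*, so
  the two trackers are compared by rotation center, not pointwise.
* **Rotation period** — mean inter-beat interval at a probe far from the
  core, cross-checked against the tip's unwrapped-angle revolution time
  (they agree to < 1% on the control spiral).
* **Periodicity / anchoring** — periodic ⇔ ibi coefficient of variation
  < 5% and a single dominant spectral line; anchored ⇔ the tip-trajectory
  centroid lies inside the patch bounding box.

## Protocols and the desk-scale configuration

* **Plane wave** — 150 pA/pF for 3 ms on the left boundary (3 columns);
  conduction-failure time budget 2L/CV_control with CV_control =
  68.3 cm/s.
* **Spiral initiation (S1–S2 parallel field)** — full scale: 600×600,
  D reduced to a quarter during initiation, S1 at t = 0, S2 = 450 pA/pF
  for 3 ms at t = 560 ms over the lower half-height from the left edge to
  2 nodes behind the −40 mV wave-back (the wave-back column is found at
  run time, which makes the placement robust across domain sizes), D
  restored at 882 ms.
* **Desk scale** — the full-scale runs exceed any reasonable interactive
  budget, so spiral work uses a 200×200 domain with D = 0.00154/4
  throughout (no further reduction during initiation) and S2 at 340 ms.
  Halving the diffusion length halves the spiral wavelength, so the 45 mm
  domain holds the rotor the way the 135 mm domain holds the full-scale
  one, while the depolarization front stays ~2 nodes wide and resolved.
  On this domain the control rotor persists for ≥ 2 s with a single tip
  and rotation period ≈ 260 ms, decreasing monotonically with zero-sided
  G_gap — the full-scale trend at desk cost.  The test suite uses this
  configuration; the full-scale protocol is the same code path.
* **Mesh control** — a 30 pA/pF, 400 ms pulse on one-node-wide grid lines
  dividing the domain into blocks² cells (4² full scale, 2² desk scale).
  Termination: every node below −40 mV with no re-excitation for 200 ms
  after the pulse (checked in 20 ms strides).
* **Two-sided conduction failure** — per-node fibroblasts at culture scale
  (6.3 pF / 4 nS) can never block conduction: the myocyte–myocyte
  equivalent coupling is D·C_m/dx² ≈ 560 nS, orders beyond the fibroblast
  load.  One- and two-sided wiring is physically meaningful for fibroblast
  *clusters* of myocyte size; the packaged failure-regime configuration
  (`two_sided_failure_coupling()`: C_f = 756 pF, G_f = 240 nS,
  E_f = −80 mV, G_ff = 20 nS, G_mf = G_fm = 150 nS) blocks plane waves at
  G_gap = 0.5 and 2 nS.  The near-rest E_f makes the cluster load the
  front without tonically depolarizing the sheet (a depolarized E_f at
  this load renders the whole sheet inexcitable instead).

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| C_f, G_f, E_f | pF, nS, mV | 6.3, 4, −49 | fibroblast load and reversal |
| N_f, g_j | –, nS | 1, 8 | fibroblast count, per-junction coupling |
| D | cm²/ms | 0.00154 | myocyte-layer diffusion (CV ≈ 68 cm/s) |
| dx, dt | mm, ms | 0.225, 0.02 | lattice and step (stability: dt ≤ dx²/4D) |
| G_ff, G_mf = G_fm | nS | 0 | fibroblast-layer and cross-layer wiring |
| activation threshold | mV | −40 | upstrokes, CV, control quiescence |
| upstroke slope | mV/ms | 5 (0.5 for spontaneous) | beat detection |
| periodicity bound | – | 5% ibi CoV | periodic/nonperiodic call |

## Known limitations

* The isolated myocyte rests at −86.4 mV (−86.2 mV published initial
  value, drifting a fraction of a mV over seconds of quiescence).  Reports
  of −84.6 mV for this cell are not reproduced by the published parameter
  set; all *differential* quantities (the composite delta table, upstroke
  deltas) are insensitive to this offset.
* Under the documented cross-coupling reading, two-sided conduction
  failure is flat or slowly varying in the on-site G_gap; a recovery of
  conduction at high G_gap (nonmonotone CV) is not reproduced.
* The desk-scale rotor is confined (wavelength comparable to the domain),
  so its tip meanders over ~10 mm rather than tracing the near-circular
  core of a large-domain rotor; tip statistics in the tests are stated for
  this regime.
* The lookup-table tissue path and the exact single-cell path differ at
  the interpolation level (~10⁻⁶); bitwise comparisons are only made
  between tissue runs.
* Synthetic inputs (piecewise-linear APs, the analytic Archimedean rotor
  field, constructed fronts) validate the *measurement* code exactly but
  do not exercise model physiology; the model-level checks are the single
  cell against its reference table and tissue against the printed control
  CV.
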