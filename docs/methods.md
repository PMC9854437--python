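# Methods

## Model overview

`perfusim` is a closed-loop, lumped-parameter (0-D) model of the adult
circulation coupled to an extracorporeal centrifugal pump.  Space is
discretised into compartments in which pressure and flow are uniform;
each compartment is an RLC element of an electric-analogue network.  The
state vector has 27 entries: four heart-chamber volumes, eighteen
vascular node volumes and five inertial branch flows.  Units are mmHg,
mL and s throughout (resistance mmHg·s/mL, inertance mmHg·s²/mL,
compliance mL/mmHg).

### Vascular network

The arterial tree is a ladder: aortic root/arch (`AA1`) → descending
aorta (`AA2`) → thoracic aorta (`AT1`) → abdominal aorta I (`AB1`) →
abdominal aorta II / iliac (`ABII`), each segment a series R(-L) into a
shunt compliance.  Peripheral beds branch off the ladder — head and arms
from the arch; splanchnic, renal and hepatic beds from `AB1`; left and
right legs from `ABII` — each bed an arterial resistance (the "variable"
resistance that calibration and the sensitivity study may scale), a bed
compliance and a venous resistance.  Head and arm beds drain into the
superior vena cava; all abdominal beds and the legs drain into an
abdominal venous collector, then the inferior vena cava, then the right
atrium.  A single resistive coronary branch connects the aortic root to
the right atrium so that coronary flow recirculates without an explicit
coronary network.  The pulmonary circulation is three RLC compartments
(arterial, capillary, venous) between the right ventricle and left
atrium.  The thoracic compartments and heart chambers sit inside a
constant intrathoracic pressure of −4 mmHg; abdominal and peripheral
compartments are at atmospheric reference.  Respiratory pressure
oscillation is not modelled (cycle-averaged quantities are the study
output).

One wiring convention to note: each ladder segment's R and L sit on the
branch *feeding* its node, so the ascending-aorta resistance `R_AA1`
lies in series with the aortic valve between the left ventricle and the
arch node.  This is also the resistance scaled by the sensitivity study,
so raising it impedes native ejection while leaving pump return paths
untouched.  An inertance on a valve branch is not supported (`L_AA1`
must remain 0); the arch inertance is carried by `L_AA2`.

### Heart

The four chambers follow the time-varying elastance model
`P = [E_min + e(t)(E_max − E_min)](V − V0) + Pt`.  The activation `e(t)`
is a half-cosine bump over the systolic interval, with
`T_sys,v = 0.3·√(60/HR)` s for the ventricles, `T_sys,a = 0.15·√(60/HR)` s
for the atria, and the atrial bump leading the ventricular one by
`AV_delay = 0.12·√(60/HR)` s.  The ECG is not modelled explicitly; the
parametric timing reproduces the same cycle-averaged behaviour.

The interventricular septum couples the ventricles through a
displacement volume `V_spt = (P_LV − P_RV)/E_spt(e)`, subtracted from the
left and added to the right free-wall volume; the three-way linear fixed
point is solved in closed form at every evaluation.  Septal elastance is
activated like the ventricles (`E_spt` 0.58–4.8 mmHg/mL, about twice the
LV free-wall stiffness, in the range classical two-ventricle
interdependence models use).  A rigid septum (`E_spt → ∞`) recovers
independent ventricles.

Valves are ideal diodes: Ohmic flow for a positive gradient, none
otherwise.  Numerically the diode is realised as the smooth conductance
ramp `Q = (ΔP + √(ΔP² + ε²))/(2R)` with ε = 1 mmHg·10⁻³, which is
strictly non-negative (zero net regurgitation holds exactly) and removes
the switching discontinuity; halving ε changes cycle means by < 0.1 %
(tested).

### Pump and cannulation

The centrifugal pump obeys the quadratic head–flow law
`ΔP = k1·ω² − k2·ω·Q − k3·Q·|Q|` (ω in rpm, Q in mL/s).  The
coefficients describe pump *plus tubing and oxygenator*, which is why
the effective internal resistance (`k2·ω`) is far larger than a bare
impeller curve.  Cannulae are resistive lines; because the pump stores
no blood, the junction is solved algebraically each evaluation: with
inlet conductance `G_in` and outlet conductance `G_out` the pump flow is
the unique root of a monotone quadratic, and the individual cannula
flows reconstruct exactly (`Σ inlet = Q = Σ outlet` to round-off, the
mass-balance invariant).  At ω = 0 check valves close every cannula and
the model is bitwise the native circulation; while the pump spins, flow
may reverse if the head cannot support the arteriovenous gradient — a
real property of valveless centrifugal circuits.

Six switches select the four supported circuits (SW1 femoral-vein
inflow, SW2 SVC inflow, SW3 carotid return, SW4 femoral-artery return,
SW5 right-atrial inflow, SW6 ascending-aorta return).  Tap points:
right atrium (chamber), SVC node, abdominal venous collector (femoral
vein), aortic root (`AA1`), head compartment (bilateral carotid return,
split symmetrically into the single head section; the carotid cannula
resistance includes the distal carotid segment), distal aorta `ABII`
(femoral artery, serving both legs).

## Parameters and calibration

No parameter table exists for the reference haemodynamic state, which is
specified instead by its outputs: HR 90 beat/min, systolic aortic
pressure 90 mmHg, mean LAP 21 mmHg, mean RAP 10 mmHg, mean PAP 18 mmHg,
CO 4.3 L/min.  The shipped default set was assembled from standard adult
0-D ranges (bed resistances encoding a brain 13 % / arms 8 % / coronary
4–8 % / splanchnic 28 % / renal 22 % / hepatic 8 % / legs 17 % flow
split) and then calibrated.  `calibrate_baseline` is a bounded,
restarted Nelder–Mead search over six scale factors — LV and RV
end-systolic elastance, systemic arterial resistance, venous compliance,
stressed blood volume, pulmonary resistance — entirely deterministic.
The resulting heart is a stiff, pressure-loaded configuration
(E_max,LV 2.37, E_min,LV 0.30, LV EDV ≈ 105 mL; RV 0.70/0.18,
EDV ≈ 82 mL) consistent with the stated operating point.

**A physical caveat:** in any passive pulmonary network the cycle-mean
PAP must exceed the cycle-mean LAP by CO × R_pulm, so the stated pair
(PAP 18 below LAP 21) cannot both be met.  The calibrator drives
pulmonary resistance toward its lower bound and down-weights the PAP
residual; PAP lands at its feasible floor ≈ 1 mmHg above LAP
(≈ 21.8 mmHg) and the residual is reported honestly.

Pump coefficients and cannula resistances are not identifiable from the
baseline; they were tuned (a separate, offline coordinate search — the
shipped `data/tuned_params.json` is one such set) against the
speed-sweep percent-change magnitudes.  Tuned values: k1 1.6·10⁻⁵,
k2 9·10⁻⁴, k3 1.4·10⁻³; cannula resistances in_RA 0.27, in_SVC 0.50,
in_FV 0.09, out_AA 0.25, out_CC 180, out_FA 1.45 mmHg·s/mL.  The large
carotid value reflects that the bilateral carotid line feeds the
post-arteriolar head node directly, so it must include the distal
arterial impedance.

## Numerics

Fixed-step classic RK4 with the step chosen to divide the beat period
exactly (default ≤ 0.2 ms, ≈ 3 334 steps per beat at HR 90), evaluated
in a numba-compiled kernel.  With the smoothed valves the system is
non-stiff at this step; halving the step changes cycle means by < 0.1 %
(tested), and fixed stepping makes every run bitwise reproducible —
there is no stochastic element anywhere in the model.  Waveforms are
recorded at 1 ms.  Volume is conserved to round-off by construction
(every branch flow enters one vertex and leaves another); the 60 s
conservation check measures ≈ 10⁻¹⁵ relative drift.

Periodic steady state is declared when the cycle means of aortic
pressure, systemic output, LAP and RAP each change by < 10⁻³ between
consecutive beats (minimum 10, maximum 200 beats; the calibrated model
converges in ≈ 20 beats).  Converged results are independent of the
starting phase within 0.1 %.  Problem sizes used by the shipped tests
and the acceptance script: single runs of 10–90 beats, a four-strategy
six-speed sweep of 25 scenarios, and calibration budgets of a few
hundred model evaluations.

Degenerate inputs: a non-finite state names the first offending variable
and the simulation time; a missing compartment or cannula raises a
configuration error naming the symbol; an unconverged record refuses to
yield PV loops.

## Cardiac output under bypass

CO is the net systemic perfusion: cycle-mean aortic-valve flow plus
every pump return entering the systemic arterial tree.  This is the only
definition that is conserved (it equals total venous return at steady
state) and lets CO rise while the left ventricle unloads.  Organ
perfusion (cerebral, renal, hepatic, splanchnic) is measured on the
venous drainage branch of each bed; SVC flow is the SVC→RA branch.

## Energetics

External work EW is the shoelace area of one converged PV loop; the
potential-energy term is the classical triangle
`PE = ESP·(ESV − V0)/2` and `PVA = EW + PE`.  Arterial elastance is
`Ea = ESP/SV`; coupling is reported as `Ea_S/Ees_Left` (left) and
`Ees_Right/Ea_P` (right), with the inverse right-sided ratio exposed as
a derived field because both conventions appear in the literature.

## Behaviour of the tuned model, and known limitations

On the tuned set the model reproduces: monotone CO gains for the
RA→AA&CC and FV→FA&CC circuits reaching ≈ +53 % and +51 % at 4 500 rpm;
a dual-drainage FV&SVC→FA&CC gain of ≈ +51 %; a peak cerebral-flow gain
of ≈ +36 % for RA→AA&CC at ≤ 3 500 rpm; and a negligible aortic-pressure
change (≈ 2 mmHg) for RA→AA&CC at 2 000 rpm.

Several behaviours reported for circuits of this kind in the clinical
simulation literature are *not* reproduced, for reasons we believe are
structural rather than a matter of tuning:

* **CO decrease under RA→FA&CC.**  At steady state the net systemic
  perfusion equals `(MAP − RAP)/SVR`; any forward-pumping venoarterial
  circuit raises MAP and lowers RAP, so CO rises.  Moving the return
  from the aortic root to the femoral artery shifts LV afterload by only
  a few mmHg in this network — far too little to collapse native output.
  Whatever mechanism produces a reported decrease (pump-inlet
  suction limitation, collapsible veins, a different CO probe) is not
  part of this model; inlet suction limitation is deliberately not
  implemented.  The model yields ≈ +47 % instead of −17 %.
* **Rising LV external work / RV pressure–volume area under RA→AA&CC.**
  These require the native ventricles to do *more* work while the pump
  drains the right atrium, i.e. a venous-return loop gain above one.
  Here the gain is slightly below one (RAP falls, LV afterload rises),
  so LV EW stays ≈ flat and RV PVA falls ≈ 20 %.
* **Negative CO change below 3 000 rpm for FV&SVC→FA&CC.**  Under a
  single quadratic head law the zero-flow threshold speeds for the
  RA→AA&CC and FV&SVC→FA&CC circuits are set by their arteriovenous
  gradients; requiring the first circuit to be neutral at 2 000 rpm and
  the second to backflow until 3 000 rpm yields contradictory bounds on
  k1.  The crossing cannot be reproduced with this pump representation.

Other limitations: linear compliances throughout (no pressure-dependent
vessel stiffening, no venous collapse); no baroreflex or autoregulation
(the "variable" resistances are constant within a run, so organ flows
track perfusion pressure more strongly than autoregulated beds would);
no wave propagation; a perfusion-conserving resistive coronary stub
rather than a coronary network; respiration reduced to a constant
intrathoracic pressure.  Passing tests therefore demonstrate fidelity of
the lumped network, heart, pump and energetics machinery at this
operating point — not clinical predictive validity for an individual
patient.
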