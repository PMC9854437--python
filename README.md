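# perfusim

Closed-loop 0-D (lumped-parameter) simulation of extracorporeal
cannulation strategies for aortic arch surgery.

During arch repair the cerebral circulation must be perfused while the
arch itself is excluded, and several cannulation set-ups are used
clinically: the pump may drain the right atrium (RA), the femoral vein
(FV) or additionally the superior vena cava (SVC), and return blood to
the ascending aorta (AA), the femoral artery (FA) and both common
carotid arteries (CC).  `perfusim` provides a quantitative test bench
for four such circuits — RA→AA&CC, RA→FA&CC, FV→FA&CC and
FV&SVC→FA&CC — on top of a complete closed-loop circulation model, for
modellers and perfusion researchers who want to compare haemodynamics,
organ perfusion and ventricular energetics across pump speeds.

## Model

* Multi-compartment RLC network: aortic ladder (root/arch, descending,
  thoracic, abdominal I/II), head, arms, splanchnic, renal, hepatic and
  two leg beds, SVC/IVC/abdominal venous collectors, a resistive
  coronary branch and a three-compartment pulmonary circulation.
* Time-varying-elastance chambers, `P = [E_min + e(t)(E_max−E_min)](V−V0) + Pt`,
  with half-cosine activation, atrial lead, ideal-diode valves
  (numerically smoothed) and septal ventricular interdependence.
* Centrifugal pump with quadratic head–flow law
  `ΔP = k1ω² − k2ωQ − k3Q|Q|`, resistive cannulae and an exactly
  mass-balanced pump junction; six switches select the circuit.
* Baseline calibration to the study operating point (HR 90 beat/min,
  AoP_sys 90 mmHg, LAP 21 mmHg, RAP 10 mmHg, PAP 18 mmHg, CO 4.3 L/min)
  by a deterministic bounded simplex search.
* PV-loop analysis: external work EW (shoelace area),
  `PVA = EW + ESP·(ESV−V0)/2`, arterial elastance `Ea = ESP/SV`,
  ventricular–arterial coupling `Ea_S/Ees_Left` and `Ees_Right/Ea_P`,
  and percent changes of every haemodynamic/energetic quantity versus
  baseline.

See `docs/methods.md` for assumptions, numerical choices and known
limitations.

## Worked example

```python
import perfusim as ps
from perfusim.analysis import summarize

params = ps.load_tuned_parameters()        # calibrated + pump-tuned set
baseline = ps.simulate(params)             # pump off, to periodic steady state
scenario = ps.simulate(params, strategy="RA_AA_CC", rpm=4500)
result = summarize(scenario, baseline, params)

print(f"baseline CO {baseline.cardiac_output():.2f} L/min, "
      f"AoP_sys {baseline.cycle_max('AoP'):.1f} mmHg")
print(f"RA->AA&CC @4500: dCO {result.change('CO'):+.1f}%, "
      f"cerebral {result.change('cerebral_flow'):+.1f}%, "
      f"pump {result.value('pump_flow'):.2f} L/min")
```

prints

```
baseline CO 4.36 L/min, AoP_sys 91.3 mmHg
RA->AA&CC @4500: dCO +52.9%, cerebral +54.5%, pump 3.19 L/min
```

i.e. at full support the right-atrial-to-aorta-and-carotid circuit adds
roughly three quarters of the baseline output as extracorporeal flow,
raising net systemic perfusion by ≈ 53 % and cerebral perfusion with it.

The same operations are available from a shell:

```sh
perfusim --tuned simulate --strategy RA_AA_CC --rpm 3000
perfusim --tuned suite --out out/              # baseline + 4 strategies x 6 speeds
perfusim --tuned sensitivity --strategy RA_FA_CC --rpm 2500 --scale 1.2
perfusim calibrate --out out/
```

`suite` writes `summary.csv` (one row per scenario, every quantity and
its percent change), per-scenario waveform CSVs and PV-loop CSVs, plus a
run log; reruns are byte-identical.

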