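# pulsewave

Arterial pressure–flow waves are continuously reflected at bifurcations,
tapers and peripheral beds; in the supine body the tree is strikingly well
matched in the forward direction while backward waves are trapped before
they reach the heart. `pulsewave` asks what happens to this favourable
configuration when the body stands up: it couples a 1D arterial-network
pulse-wave solver (gravity via Stevino's law, RCR Windkessel terminals,
pressure-stiffening viscoelastic walls) with a static head-up-tilt
transform and the classical wave-analysis toolkit, and compares converged
supine (0°) and standing (90°) beats.

The analysis chain implements:

* **wave separation** — P_f,b = (P ± Z_c·Q)/2, Q_f,b = (Q ± P/Z_c)/2, with
  Z_c from the PQ-loop and local wave speed c from the PU-loop
  (early-systolic slope of the loop's linear tract);
* **reflection indices** — RM = PP_b/PP_f, RI = RM/(1+RM), augmentation
  index AI = AP/PP;
* **reflection coefficients** — R_p = (Z_d − Z_p)/(Z_d + Z_p) at
  bifurcations (forward and backward), the telescoped taper sum
  Σ (Z_{e+1}−Z_e)/(Z_{e+1}+Z_e), and
  (R_down − Z_c,out)/(R_down + Z_c,out) at terminals;
* **wave intensity** — WI_f,b = ±(1/4ρc)(dP/dt ± ρc·dU/dt)², with
  FCW/FDW/BCW/BDW peak classification;
* **wave trapping** — per aortic site, the time of reflection
  ToR = t_back − t_FCW with t_back = ∫t·WI_b dt / ∫WI_b dt, and the point
  of reflection PoR = ToR·c̄_down/2, whose downstream drift along the
  aorta is the "moving horizon" signature of backward wave trapping;
* **statistics** — exact paired Wilcoxon signed-rank tests over vessel
  segments and ANCOVA on arrival-time regression lines.

The standing state applies the steady-state head-up-tilt shifts
(HR +23%, SV −32%, TPR +39%, cerebral arteriolar resistance −12%,
cerebral compliance +65%, venous/venular compliance −25%) and lets the
hydrostatic field act along every inclined vessel; wave-speed changes are
*emergent* from the distension-stiffening tube law, not imposed.

## Worked example

```python
from pulsewave import SimConfig, STANDING, SUPINE, apply_posture, simulate_beats
from pulsewave.fixtures import default_inflow, make_canonical_networks
from pulsewave.report import vessel_wave_report, posture_comparison_report

base = make_canonical_networks("mini_aorta")     # 20-vessel adult tree
inflow = default_inflow("mini_aorta")            # 70 ml half-sine, RR 0.8 s

net_sup, inf_sup, _ = apply_posture(base, inflow, SUPINE)
res_sup = simulate_beats(net_sup, inf_sup, SUPINE, SimConfig())
net_std, inf_std, _ = apply_posture(base, inflow, STANDING)
res_std = simulate_beats(net_std, inf_std, STANDING, SimConfig())

rep = posture_comparison_report(res_sup, res_std, net_sup, net_std, 1050.0)
print(rep[rep.metric == "c_m_s"][["vessel_id", "supine", "standing",
                                  "delta_pct", "p_value", "n"]])
```

prints (abridged) the per-vessel PU-loop wave speeds with paired exact
Wilcoxon p-values over the vessel segments:

```
    vessel_id  supine  standing  delta_pct  p_value   n
8          13   7.503     7.207     -3.954    0.031   6   # carotid: slows
16         18   4.873     5.584     14.600    0.002  10   # thoracic aorta
48         41   5.574     6.559     17.664    0.125   4   # iliac bifurcation
60         48   8.831     9.261      4.875    0.002  10   # tibial
```

Standing raises wave speed at every aortic and leg site below heart level
and lowers it in the elevated, autoregulation-dilated cerebral branch; the
iliac row is not significant because its four segments bound the exact
two-sided p at 0.125. The same pair of beats feeds the reflection
(`vessel_wave_report`, `reflection_coefficient_report`) and trapping
(`pulsewave.intensity.reflection_horizon`) tables.

The `analysis/` scripts run the full study as a pipeline
(`01_simulate_postures.py` → `04_posture_stats.py`, outputs under
`results/`), and the same steps are available from a shell via the
`pulsewave` CLI (`simulate`, `analyze`, `wia`, `trapping`,
`compare-posture`, `fixtures`).

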