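#!/usr/bin/env python
"""Wave analysis of the converged supine and standing beats.

Per posture: per-vessel wave speed, characteristic impedance, forward and
backward pulse pressures, RM/RI/AI and taper reflection coefficients, plus
the bifurcation and terminal reflection-coefficient tables.

Reads results/waves_{supine,standing}/; writes the report CSVs next to them.
"""

from pathlib import Path

from pulsewave.io import FLOAT_FMT, read_network, read_waveforms
from pulsewave.report import reflection_coefficient_report, vessel_wave_report

RESULTS = Path(__file__).resolve().parent.parent / "results"
RHO = 1050.0


def main():
    for posture in ("supine", "standing"):
        waves = RESULTS / f"waves_{posture}"
        result = read_waveforms(waves)
        network = read_network(waves / "network.json")
        vessel = vessel_wave_report(result, network, RHO)
        bif, term = reflection_coefficient_report(result, network)
        vessel.to_csv(waves / "vessel_report.csv", index=False,
                      float_format=FLOAT_FMT)
        bif.to_csv(waves / "bifurcation_rp.csv", index=False,
                   float_format=FLOAT_FMT)
        term.to_csv(waves / "terminal_rp.csv", index=False,
                    float_format=FLOAT_FMT)
        aorta = vessel[vessel.group == "aortic"]
        print(f"{posture}: aortic c {aorta.c_m_s.min():.2f}-"
              f"{aorta.c_m_s.max():.2f} m/s, "
              f"RM at ascending aorta "
              f"{vessel.set_index('vessel_id').loc[63, 'RM']:.3f}, "
              f"terminal R_p {term.rp_terminal.min():.2f}-"
              f"{term.rp_terminal.max():.2f}")


if __name__ == "__main__":
    main()
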