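"""Conductivity and TEED dosimetry from the published measurement inputs.

Computes the tissue conductivity implied by the in vivo two-electrode
impedance measurement, then the electrical energy delivered by the
strongest stimulation protocol and its safety margin.
"""

import optrodesim as osim

# microelectrode disc: radius 8 um; three-figure pi reproduces the printed area
area = osim.electrode_area(8e-6, paper_pi=True)
print(f"electrode area: {area * 1e12:.3f} um^2")

meas = osim.ImpedanceMeasurement(resistance_ohm=0.543e6, separation_m=450e-6,
                                 electrode_area_m2=area)
k = osim.conductivity_from_impedance(meas)
print(f"in vivo conductivity K = D/(R S) = {k:.3f} S/m")

protocol = osim.StimulationProtocol(current_a=300e-6, pulse_width_s=0.4e-3,
                                    frequency_hz=3.0, duration_s=20.0)
result = osim.total_energy_and_check(protocol, resistance_ohm=5.43e5)
print(f"TEED at 300 uA: {result.energy_per_second_j:.3e} J per second")
print(f"20-s train total: {result.total_energy_j:.3e} J "
      f"(limit {result.safety_limit_j:.2e} J, within: {result.within_limit})")

# K ~ 4.12 S/m parameterizes the stimulation field; the 300 uA train stays
# an order of magnitude below the charge-capacity energy ceiling.
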