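"""Run the thermal release-circuit digital twin by itself.

Nine 330 Ω resistors in parallel across 5 V dissipate ~0.68 W; a
hysteresis controller reads the surface temperature through a noisy,
quantized linear sensor and holds the heated surface just below 40 °C —
inside the 37-40 °C gelatin transition window, never above 41 °C.
"""

from glucoloop.htrc import (
    ResistorNetwork,
    ThermalPlant,
    joule_power,
    plateau_temperature_c,
    simulate_htrc,
)

net = ResistorNetwork()
per_w, total_w = joule_power(net, 1.0)
print(f"ladder at full duty: {per_w * 1000:.1f} mW per resistor "
      f"(rating {net.power_rating_w * 1000:.0f} mW), total {total_w:.3f} W")

plant = ThermalPlant()
print(f"uncontrolled steady state: {plant.steady_state_c(total_w):.1f} °C")

ts = simulate_htrc(duration_s=600.0, seed=1)
print(f"closed loop from {plant.ambient_c:.0f} °C ambient over 600 s:")
print(f"  max temperature: {ts['temp_C'].max():.2f} °C (safety bound 41 °C)")
print(f"  plateau (final 120 s mean): {plateau_temperature_c(ts):.2f} °C")
print(f"  release fraction at end: {ts['release_fraction'].iloc[-1]:.3f}")
# the plateau rounds to 40 °C: the heater is sized so full power lands the
# surface at the top of the gelatin window and the controller guards it
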