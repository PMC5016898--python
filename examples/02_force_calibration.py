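"""Calibrate the ODEP force model and explore the operating window.

The four printed 8-V maximum manipulation velocities anchor the model;
the script then shows the live/dead Clausius-Mossotti contrast at the
100 kHz operating point, the exact voltage-squared scaling, and the
escape-velocity table that drives the sorting protocol.
"""

import numpy as np

import odepsim as o

medium = o.MediumProps()
print("Clausius-Mossotti factor at 100 kHz, 3.4 uS/cm:")
for name, make in (("live cancer", o.live_cancer_cell),
                   ("dead cancer", o.dead_cancer_cell),
                   ("live leukocyte", o.live_leukocyte),
                   ("dead leukocyte", o.dead_leukocyte)):
    k = o.clausius_mossotti(make(), medium, 1e5)
    kind = "pDEP (pulled)" if k.real > 0 else "nDEP (pushed)"
    print(f"  {name:15s} Re[K] = {k.real:+.3f}  -> {kind}")

model = o.calibrate_force_model()
print("\ncalibration anchors (8 V):")
print(model.calibration_report.to_string(index=False))

bar = o.LightPattern(kind="bar", bandwidth=150.0)
circ = o.LightPattern(kind="hollow_circle", bandwidth=40.0)
print("\nmax manipulation velocity vs voltage (live cancer, 40-um circle):")
for v in (2.0, 4.0, 8.0):
    vmax = o.max_manipulation_velocity(o.live_cancer_cell(), circ,
                                       o.ODEPConfig(voltage=v), model)
    print(f"  {v:4.1f} V -> {vmax:7.2f} um/s   (= (V/8)^2 x 290.01)")

print("\nnet manipulation force at the 8-V anchors (Stokes' law):")
for cell, v in ((o.live_cancer_cell(), 290.01), (o.live_leukocyte(), 250.49)):
    F = o.manipulation_force_from_velocity(cell, medium, v)
    print(f"  {cell.cell_type:9s} r={cell.radius:4.1f} um, "
          f"v={v:6.2f} um/s -> F = {F:.2e} N")
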