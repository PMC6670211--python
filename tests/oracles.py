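"""Independent oracles used by the tests.

These deliberately bypass the ODE machinery: the steady-state prediction is
obtained from a time-averaged algebraic balance solved by plain bisection, so
it shares no code path with the simulator it cross-checks.
"""


def dutycycle_ss_nh3_mm(scenario, tol: float = 1e-12) -> float:
    """Algebraic steady-state ammonia from the duty-cycle balance, in mM.

    With the glutamine loop closed (GLUL production balancing GLS
    consumption over a cycle), the time-averaged ammonia balance reduces to

        duty * 2 * vmax_cps1 * x / (km + x) = v_nh3_abs - v_nh3_ex

    where duty is the fraction of the cycle with CPS1 active (2.87/4.3).
    Solved for x by bisection on [0, 100] mM.
    """
    k = scenario.kinetics
    duty = 2.87 / 4.3
    target = k.v_nh3_abs - k.v_nh3_ex

    def f(x):
        return duty * 2.0 * k.vmax_cps1 * x / (k.km_nh3_cps1 + x) - target

    lo, hi = 0.0, 100.0
    if f(hi) <= 0:
        raise ValueError("CPS1 capacity cannot balance the nitrogen influx")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
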