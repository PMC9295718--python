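"""Independent oracles for cross-checking the simulator.

These are deliberately naive, spreadsheet-style recursions written in
plain Python (no numpy, no imports from the package) so they share no
code with the implementation they check.
"""

import math


def pulse_on(t, start, duration, repeat_time, end):
    """Brute-force pulse-train indicator: enumerate windows until past t."""
    k = 0
    while start + k * repeat_time <= t:
        lo = start + k * repeat_time
        if lo <= t < lo + duration and t < end:
            return 1
        k += 1
    return 0


def manual_euler(
    n_steps,
    s0=2.71,
    expected_stress=0.0,
    equilibrium=0.0,
    rate=0.5,
    c_appraisal=0.23,
    c_strain=0.29,
    w_coping=0.29,
    w_ocb=0.2,
    exchange=0.51,
    expected_satisfaction0=0.0,
    workload=0.0,
    frequency=0.0,
    restored=1.0,
    other=0.5,
    dt=1.0,
):
    """Hand-rolled Euler recursion with constant (mean-mode) resources.

    Returns one dict per step holding the stocks *before* the step and
    every auxiliary evaluated at it.
    """
    stressor, satisfaction, resource, expected_sat = s0, equilibrium, 0.0, expected_satisfaction0
    rows = []
    t = 0.0
    for _ in range(n_steps):
        perceived = stressor
        if perceived - expected_stress > 0:
            disc = perceived - expected_stress
        elif perceived > 0:
            disc = (perceived - expected_stress) / 2
        else:
            disc = -expected_stress / 2
        appraisal = disc * c_appraisal if disc > 0 else 0.0
        strain = disc * c_strain if disc > 0 else 0.0
        if resource > 0:
            wc, wo = w_coping, w_ocb
        else:
            wc = w_coping + w_coping * (-resource) / (1 - resource)
            wo = w_ocb / (1 - resource)
        if disc > 0:
            coping = (1 + disc) * wc
        elif perceived > 0:
            coping = math.exp(disc) * wc
        else:
            coping = 0.0
        sat_disc = satisfaction - expected_sat if satisfaction > expected_sat else 0.0
        obligation = sat_disc * exchange
        ocb = obligation * wo
        if frequency > 0:
            increment = workload * pulse_on(t, 1.0, 1.0, 100.0 / frequency, 100.0)
        else:
            increment = 0.0
        rows.append({
            "time": t,
            "challenge_stressor": stressor,
            "job_satisfaction": satisfaction,
            "resource_difference": resource,
            "expected_satisfaction": expected_sat,
            "stress_discrepancy": disc,
            "challenge_appraisal": appraisal,
            "strain": strain,
            "importance_coping": wc,
            "importance_ocb": wo,
            "coping": coping,
            "satisfaction_discrepancy": sat_disc,
            "felt_obligation": obligation,
            "ocb": ocb,
            "task_increment": increment,
        })
        stressor = stressor + dt * (increment - coping)
        satisfaction = satisfaction + dt * (appraisal - strain + (equilibrium - satisfaction) * rate)
        resource = resource + dt * (restored - coping - ocb - other)
        expected_sat = expected_sat + dt * (ocb * exchange)
        t += dt
    return rows
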