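"""Compiled inner loops for the generative simulators.

The two-state switching simulator is an exact continuous-time scheme built
on competing exponential clocks; the depletion-replenishment simulator is a
fixed-step Monte Carlo (reference step 0.001 ms).  Both are seeded through
numpy's legacy global generator inside the jitted function, which numba
supports and which keeps runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["switching_kernel", "depletion_kernel"]


@njit(cache=True)
def switching_kernel(
    k_sf, k_fs, tau_fast, tau_slow, t_abs, tau_rel,
    n_isis, seed, init_state, record_switches,
):
    """Exact two-state switching simulation.

    States: 0 = slow, 1 = fast.  During every wait (refractory or
    excitation) the state continues to evolve; on a mid-wait switch the
    release clock is redrawn at the new state's rate, which is exact by
    memorylessness.  Returns (isis, state_at_spike, switch_times, n_switch,
    truncated_flag); state_at_spike is the state at the moment the release
    fired.
    """
    np.random.seed(seed)
    isis = np.empty(n_isis)
    state_at_spike = np.empty(n_isis, dtype=np.int64)
    cap = 4 * n_isis + 1024
    switch_times = np.empty(cap if record_switches else 1)
    n_switch = 0
    truncated = False

    state = init_state
    t = 0.0
    for i in range(n_isis):
        t_start = t
        # refractory: duration fixed up-front, state evolves underneath
        dur = t_abs
        if tau_rel > 0.0:
            dur += np.random.exponential(tau_rel)
        t_end_refr = t + dur
        while True:
            rate_out = k_sf if state == 0 else k_fs
            if rate_out <= 0.0:
                break
            w = np.random.exponential(1.0 / rate_out)
            if t + w >= t_end_refr:
                break
            t += w
            state = 1 - state
            if record_switches:
                if n_switch < cap:
                    switch_times[n_switch] = t
                    n_switch += 1
                else:
                    truncated = True
        t = t_end_refr
        # excitation: competing release vs switch clocks
        while True:
            tau_state = tau_slow if state == 0 else tau_fast
            w_rel = np.random.exponential(tau_state)
            rate_out = k_sf if state == 0 else k_fs
            w_sw = np.inf
            if rate_out > 0.0:
                w_sw = np.random.exponential(1.0 / rate_out)
            if w_rel <= w_sw:
                t += w_rel
                break
            t += w_sw
            state = 1 - state
            if record_switches:
                if n_switch < cap:
                    switch_times[n_switch] = t
                    n_switch += 1
                else:
                    truncated = True
        isis[i] = t - t_start
        state_at_spike[i] = state
    return isis, state_at_spike, switch_times[:n_switch], n_switch, truncated


@njit(cache=True)
def depletion_kernel(
    p_depl, tau_repl, n_max,            # per-source parameter arrays
    t_dead, t_rel_mean,                 # refractory parameters
    n_isis, dt, seed,
    literal_update,                     # compounding pool update if True
    release_cap,                        # 0: do not record releases
    deplete_during_refractory,          # releases in refractoriness deplete
):
    """Fixed-step depletion-replenishment Monte Carlo.

    Per step and per source k, a release occurs iff a uniform draw is below
    ``p_depl[k] * n[k] * dt``; the pool then drops by 1 (floored at 0) and
    the source's release clock resets.  Otherwise the pool relaxes toward
    ``n_max[k]`` with timescale ``tau_repl[k]`` (default scheme), or is
    updated by the compounding closed-form increment anchored at the last
    release when ``literal_update`` is set.  A release triggers a spike
    only outside the refractory period; each spike starts a new refractory
    interval ``t_dead + Exp(t_rel_mean)``.

    Returns (spike_times, releases[:n_rel], n_rel, release_truncated).
    """
    np.random.seed(seed)
    K = p_depl.size
    n = n_max.copy().astype(np.float64)
    t_rel_last = np.zeros(K)
    relax = np.empty(K)
    for k in range(K):
        relax[k] = 1.0 - np.exp(-dt / tau_repl[k])

    spikes = np.empty(n_isis + 1)
    n_spikes = 0
    releases = np.empty(release_cap if release_cap > 0 else 1)
    n_rel = 0
    rel_truncated = False

    t = 0.0
    refr_until = 0.0
    while n_spikes < n_isis + 1:
        t += dt
        in_refr = t < refr_until
        for k in range(K):
            r = np.random.random()
            if (not in_refr or deplete_during_refractory) and r < p_depl[
                k
            ] * n[k] * dt:
                n[k] = max(n[k] - 1.0, 0.0)
                t_rel_last[k] = t
                if release_cap > 0:
                    if n_rel < release_cap:
                        releases[n_rel] = t
                        n_rel += 1
                    else:
                        rel_truncated = True
                if not in_refr:
                    spikes[n_spikes] = t
                    n_spikes += 1
                    refr_until = t + t_dead
                    if t_rel_mean > 0.0:
                        refr_until += np.random.exponential(t_rel_mean)
                    if n_spikes >= n_isis + 1:
                        break
                    in_refr = True
            else:
                if literal_update:
                    n[k] = n[k] + (n_max[k] - n[k]) * (
                        1.0 - np.exp(-(t - t_rel_last[k]) / tau_repl[k])
                    )
                else:
                    n[k] = n[k] + (n_max[k] - n[k]) * relax[k]
    return spikes, releases[:n_rel], n_rel, rel_truncated
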