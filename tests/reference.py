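"""Naive day-by-day reference implementation of the growth recurrence.

Deliberately written as a plain scalar loop with the closed forms inlined,
independent of the package's vectorized simulator, to serve as a
brute-force oracle for trajectory tests.
"""

import math


def naive_safy(d0, elue, stt, rg, ta, *, k_ext=0.5, eps_c=0.48, sla=0.022,
               pl_a=0.15, pl_b=0.002, rs=6000.0, py=0.005,
               t_min=0.0, t_opt=15.0, t_max=37.0, beta_t=2.0, dam0=4.2):
    """Return per-day lists (dam, lai, gy, smt) for season days 1..len(rg)."""
    n = len(rg)
    dam = lai = gy = smt = 0.0
    out = {"dam": [], "lai": [], "gy": [], "smt": []}

    def ft(t):
        if t <= t_min or t >= t_max:
            return 0.0
        if t <= t_opt:
            v = 1.0 - ((t_opt - t) / (t_opt - t_min)) ** beta_t
        else:
            v = 1.0 - ((t - t_opt) / (t_max - t_opt)) ** beta_t
        return min(max(v, 0.0), 1.0)

    if pl_a >= 1.0:
        grain_start = 0.0
    elif pl_a <= 0.0 or pl_b <= 0.0:
        grain_start = math.inf
    else:
        grain_start = math.log(1.0 / pl_a) / pl_b

    for day in range(1, n + 1):
        if day < d0:
            pass
        elif day == d0:
            dam = dam0
            lai = dam0 * min(max(1.0 - pl_a, 0.0), 1.0) * sla
            smt = max(ta[day - 1], 0.0)
        else:
            r, t = rg[day - 1], ta[day - 1]
            d_dam = max(r * eps_c * (1.0 - math.exp(-k_ext * lai)) * elue * ft(t), 0.0)
            pl = min(max(1.0 - pl_a * math.exp(pl_b * smt), 0.0), 1.0)
            d_lai = d_dam * pl * sla
            if smt > stt:
                d_lai -= lai * (smt - stt) / rs
            dam = dam + d_dam
            new_lai = max(lai + d_lai, 0.0)
            if smt >= grain_start:
                gy = gy + dam * py
            lai = new_lai
            smt = smt + max(t, 0.0)
        out["dam"].append(dam)
        out["lai"].append(lai)
        out["gy"].append(gy)
        out["smt"].append(smt)
    return out
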