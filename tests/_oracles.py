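"""Independent brute-force oracles for the configuration statistics.

These deliberately share no code with the dynamic program: every
configuration of non-overlapping placements is enumerated explicitly and
its Boltzmann weight assembled factor by factor.
"""

import itertools

import numpy as np


def enumerate_configurations(table, c1, c2, c3):
    """(Z_on, Z_off, occupancy[t, s], p_on) by exhaustive enumeration."""
    conc = [c1, c2, c3]
    placements = []
    for t in range(3):
        for s in range(table.n_pos):
            if table.inv_kd[t, s] > 0 and conc[t] > 0:
                placements.append((s, s + table.l_tf, t, conc[t] * table.inv_kd[t, s]))
    fp_start, fp_end = table.footprint
    params = table.params
    z_on = 0.0
    z_off = 0.0
    occ_num = np.zeros((3, table.n_pos))
    p_on_num = 0.0
    for r in range(len(placements) + 1):
        for combo in itertools.combinations(placements, r):
            combo = sorted(combo)
            if any(a[1] > b[0] for a, b in zip(combo, combo[1:])):
                continue  # steric overlap
            w = 1.0
            for p in combo:
                w *= p[3]
            # nearest-neighbour cooperativity along the chain
            for a, b in zip(combo, combo[1:]):
                if b[0] - a[1] <= params.d_coop:
                    w *= params.omega_coop
            z_off += w
            for p in combo:
                occ_num[p[2], p[0]] += w
            # RNAP-bound states: exclusion and recruitment
            if any(p[1] > fp_start and p[0] < fp_end for p in combo):
                continue
            w_on = w * table.q_r
            for p in combo:
                gap = fp_start - p[1] if p[1] <= fp_start else p[0] - fp_end
                if 0 <= gap <= params.d_act:
                    w_on *= params.omega_act
            z_on += w_on
            p_on_num += w_on
            for p in combo:
                occ_num[p[2], p[0]] += w_on
    z_tot = z_on + z_off
    return z_on, z_off, occ_num / z_tot, p_on_num / z_tot


def random_toy_table(rng, max_sites=5):
    """A random small explicit system suitable for exhaustive enumeration."""
    from cisevolve.thermodynamic_model import SiteTable, ThermoParams

    l_tf = int(rng.integers(5, 9))
    l_cis = 40
    n_pos = l_cis - l_tf + 1
    inv_kd = np.zeros((3, n_pos))
    for _ in range(int(rng.integers(2, max_sites + 1))):
        inv_kd[int(rng.integers(3)), int(rng.integers(n_pos))] = 10 ** rng.uniform(-4, -0.5)
    params = ThermoParams(
        omega_coop=float(rng.uniform(1, 80)),
        omega_act=float(rng.uniform(1, 80)),
        d_coop=int(rng.integers(0, 19)),
        d_act=int(rng.integers(0, 21)),
    )
    return SiteTable(
        l_cis=l_cis, l_tf=l_tf, inv_kd=inv_kd,
        q_r=float(10 ** rng.uniform(-3, 1)), params=params,
    )
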