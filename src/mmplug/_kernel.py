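"""Compiled fixed-step RK4 kernel.

Hot loop for :func:`mmplug.integrator.simulate`.  The arithmetic here mirrors
the reference rate laws in :mod:`mmplug.model` expression for expression; the
pure-Python path in the integrator exists to cross-check this kernel and the
two are held to agreement in the test suite.

State vector layout (``nf`` = total particle fractions over all plugs)::

    y = [ Xs[0..nf) | Xd | Xp | Xt | eliminated, firstpass ]

Schedules (ka, solubility, volume) arrive flattened per plug: a baseline
array plus a stacked ``(m, 4)`` segment table with CSR-style offsets.

Status codes returned: 0 ok, 1 non-finite derivative, 2 negative mass beyond
the instability threshold.
"""

import numpy as np
from numba import njit

SNAP = 1e-12  # mg; solid below this is folded into the dissolved pool


@njit(cache=True, inline="always")
def _sched(t, base, segs, lo, hi, smooth):
    val = base
    for k in range(lo, hi):
        t0 = segs[k, 0]
        t1 = segs[k, 1]
        if t < t0:
            break
        if t < t1:
            if smooth:
                x = (t - t0) / (t1 - t0)
                return segs[k, 2] + (segs[k, 3] - segs[k, 2]) * 0.5 * (1.0 - np.cos(np.pi * x))
            # abrupt variant switches at the window midpoint (centroid-preserving)
            return segs[k, 3] if t >= 0.5 * (t0 + t1) else segs[k, 2]
        val = segs[k, 3]
    return val


@njit(cache=True)
def _rhs(t, y, dy, nf, frac_plug, r0, x0,
         D, rho, hmax, ke, k12, k21, f_plug,
         ka_base, ka_segs, ka_off, ka_smooth,
         cs_base, cs_segs, cs_off,
         v_base, v_segs, v_off,
         sink, clamp_super,
         ka_p, cs_p, v_p, xd_tot):
    npg = ka_base.shape[0]
    for p in range(npg):
        ka_p[p] = _sched(t, ka_base[p], ka_segs, ka_off[p], ka_off[p + 1], ka_smooth)
        cs_p[p] = _sched(t, cs_base[p], cs_segs, cs_off[p], cs_off[p + 1], True)
        v_p[p] = _sched(t, v_base[p], v_segs, v_off[p], v_off[p + 1], True)
        xd_tot[p] = 0.0
    for f in range(nf):
        xd = y[nf + f]
        if xd > 0.0:
            xd_tot[frac_plug[f]] += xd
    elim = 0.0
    fp = 0.0
    for f in range(nf):
        p = frac_plug[f]
        xs = y[f]
        xd = y[nf + f]
        xp = y[2 * nf + f]
        xt = y[3 * nf + f]
        rate = 0.0
        if xs > 0.0 and x0[f] > 0.0:
            if sink:
                drive = cs_p[p]
            else:
                drive = cs_p[p] - xd_tot[p] / v_p[p]
            if drive != 0.0:
                xs_c = xs if xs < x0[f] else x0[f]
                r = r0[f] * np.cbrt(xs_c / x0[f])
                h = r if r < hmax else hmax
                if h > 0.0:
                    rate = (
                        -(3.0 * D / (rho * h * r0[f]))
                        * np.cbrt(x0[f])
                        * np.cbrt(xs) ** 2
                        * drive
                    )
                if rate > 0.0 and (clamp_super or xs >= x0[f]):
                    rate = 0.0
        ka = ka_p[p]
        dy[f] = rate
        dy[nf + f] = -rate - ka * xd
        dy[2 * nf + f] = f_plug[p] * ka * xd - (k12 + ke) * xp + k21 * xt
        dy[3 * nf + f] = k12 * xp - k21 * xt
        elim += ke * xp
        fp += (1.0 - f_plug[p]) * ka * xd
    dy[4 * nf] = elim
    dy[4 * nf + 1] = fp


@njit(cache=True)
def run_kernel(y0, frac_plug, r0, x0,
               D, rho, hmax, ke, k12, k21, f_plug,
               ka_base, ka_segs, ka_off, ka_smooth,
               cs_base, cs_segs, cs_off,
               v_base, v_segs, v_off,
               sink, clamp_super,
               dt, n_steps, dt_last, record_every,
               instab):
    nf = frac_plug.shape[0]
    npg = ka_base.shape[0]
    ny = 4 * nf + 2

    n_total = n_steps + (1 if dt_last > 0.0 else 0)
    n_rec = n_steps // record_every + 2 + (1 if dt_last > 0.0 else 0)
    times = np.empty(n_rec)
    xs_rec = np.empty((n_rec, npg))
    xd_rec = np.empty((n_rec, npg))
    xp_rec = np.empty((n_rec, npg))
    xt_rec = np.empty((n_rec, npg))
    el_rec = np.empty(n_rec)
    fp_rec = np.empty(n_rec)

    y = y0.copy()
    k1 = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    yt = np.empty(ny)
    ka_p = np.empty(npg)
    cs_p = np.empty(npg)
    v_p = np.empty(npg)
    xd_tot = np.empty(npg)

    status = 0
    t_fail = 0.0
    max_neg = 0.0

    irec = 0

    # record initial state
    times[irec] = 0.0
    for p in range(npg):
        xs_rec[irec, p] = 0.0
        xd_rec[irec, p] = 0.0
        xp_rec[irec, p] = 0.0
        xt_rec[irec, p] = 0.0
    for f in range(nf):
        p = frac_plug[f]
        xs_rec[irec, p] += y[f]
        xd_rec[irec, p] += y[nf + f]
        xp_rec[irec, p] += y[2 * nf + f]
        xt_rec[irec, p] += y[3 * nf + f]
    el_rec[irec] = y[4 * nf]
    fp_rec[irec] = y[4 * nf + 1]
    irec += 1

    for s in range(n_total):
        if s < n_steps:
            h = dt
            t = s * dt
        else:
            h = dt_last
            t = n_steps * dt

        _rhs(t, y, k1, nf, frac_plug, r0, x0, D, rho, hmax, ke, k12, k21, f_plug,
             ka_base, ka_segs, ka_off, ka_smooth, cs_base, cs_segs, cs_off,
             v_base, v_segs, v_off, sink, clamp_super, ka_p, cs_p, v_p, xd_tot)
        for i in range(ny):
            yt[i] = y[i] + 0.5 * h * k1[i]
        _rhs(t + 0.5 * h, yt, k2, nf, frac_plug, r0, x0, D, rho, hmax, ke, k12, k21,
             f_plug, ka_base, ka_segs, ka_off, ka_smooth, cs_base, cs_segs, cs_off,
             v_base, v_segs, v_off, sink, clamp_super, ka_p, cs_p, v_p, xd_tot)
        for i in range(ny):
            yt[i] = y[i] + 0.5 * h * k2[i]
        _rhs(t + 0.5 * h, yt, k3, nf, frac_plug, r0, x0, D, rho, hmax, ke, k12, k21,
             f_plug, ka_base, ka_segs, ka_off, ka_smooth, cs_base, cs_segs, cs_off,
             v_base, v_segs, v_off, sink, clamp_super, ka_p, cs_p, v_p, xd_tot)
        for i in range(ny):
            yt[i] = y[i] + h * k3[i]
        _rhs(t + h, yt, k4, nf, frac_plug, r0, x0, D, rho, hmax, ke, k12, k21,
             f_plug, ka_base, ka_segs, ka_off, ka_smooth, cs_base, cs_segs, cs_off,
             v_base, v_segs, v_off, sink, clamp_super, ka_p, cs_p, v_p, xd_tot)
        ok = True
        for i in range(ny):
            d = (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not np.isfinite(d):
                ok = False
            y[i] += d
        t_new = t + h
        if not ok:
            status = 1
            t_fail = t_new
            break

        # post-step fix-up.  A solid mass driven below zero within a step is
        # mass that actually left the solid: fold it into the dissolved pool
        # so the ledger stays exact.  Tiny positive remnants are snapped the
        # same way.  Other components get a plain non-negativity clamp.
        for f in range(nf):
            xs = y[f]
            if xs < SNAP:
                if xs < -instab:
                    status = 2
                    t_fail = t_new
                if xs != 0.0:
                    if -xs > max_neg:
                        max_neg = -xs
                    y[nf + f] += xs
                    y[f] = 0.0
            elif xs > x0[f]:
                y[nf + f] += xs - x0[f]
                y[f] = x0[f]
            for blk in range(1, 4):
                v = y[blk * nf + f]
                if v < 0.0:
                    if v < -instab:
                        status = 2
                        t_fail = t_new
                    y[blk * nf + f] = 0.0
        if status != 0:
            break

        last = s == n_total - 1
        if (s + 1) % record_every == 0 or last:
            times[irec] = t_new
            for p in range(npg):
                xs_rec[irec, p] = 0.0
                xd_rec[irec, p] = 0.0
                xp_rec[irec, p] = 0.0
                xt_rec[irec, p] = 0.0
            for f in range(nf):
                p = frac_plug[f]
                xs_rec[irec, p] += y[f]
                xd_rec[irec, p] += y[nf + f]
                xp_rec[irec, p] += y[2 * nf + f]
                xt_rec[irec, p] += y[3 * nf + f]
            el_rec[irec] = y[4 * nf]
            fp_rec[irec] = y[4 * nf + 1]
            irec += 1

    return (status, t_fail, max_neg, irec, times, xs_rec, xd_rec, xp_rec,
            xt_rec, el_rec, fp_rec, y)
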