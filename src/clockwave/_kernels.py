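"""Numba-compiled kernels for SDE integration, period extraction and sampling.

Everything here is an implementation detail behind the public modules.  The
kernels exist because the workloads — millions of Euler–Maruyama steps and
Gibbs chains evaluating tens of millions of closed-form CV values — are far
outside interpreted-loop territory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi

# A sentinel large CV used by sampling kernels for degenerate functions
# (all-zero coefficients, no oscillation, ill-conditioned checkpoint).
# exp(-INF_CV) underflows to an exact zero weight.
INF_CV = 1.0e30


# ---------------------------------------------------------------------------
# Euler–Maruyama integrators
# ---------------------------------------------------------------------------

@njit(cache=True)
def phase_em(n_steps, dt, omega, epsilon, D, A, B, alpha, beta, k,
             theta0, x0, seed):
    """Integrate the phase-oscillator + reporter system.

    theta' = omega + epsilon*sqrt(D)*xi(t),  x' = alpha + beta*f(theta) - k*x.

    Returns the unwrapped phase and reporter arrays (length n_steps + 1).
    """
    np.random.seed(seed)
    H = A.shape[0]
    theta = np.empty(n_steps + 1)
    x = np.empty(n_steps + 1)
    theta[0] = theta0
    x[0] = x0
    noise = epsilon * np.sqrt(D) * np.sqrt(dt)
    for n in range(n_steps):
        th = theta[n]
        f = 0.0
        for i in range(1, H + 1):
            f += A[i - 1] * np.cos(i * th) + B[i - 1] * np.sin(i * th)
        x[n + 1] = x[n] + (alpha + beta * f - k * x[n]) * dt
        if epsilon > 0.0:
            theta[n + 1] = th + omega * dt + noise * np.random.standard_normal()
        else:
            theta[n + 1] = th + omega * dt
    return theta, x


@njit(cache=True)
def goodwin_em(n_steps, dt, tau, m, ku, kv, kw, alpha, beta, k,
               epsilon, D, coef, powr, regulator, u0, v0, w0, x0, seed):
    """Integrate the Goodwin clock + reporter system.

    The clock equations carry the 1/tau time rescaling, so in the integrated
    (rescaled) time one clock period is ~1.  Gene-expression noise enters the
    mRNA (u) equation only.  ``regulator`` selects which clock variable drives
    the output: 0 = u, 1 = v, 2 = w.
    """
    np.random.seed(seed)
    u = np.empty(n_steps + 1)
    v = np.empty(n_steps + 1)
    w = np.empty(n_steps + 1)
    x = np.empty(n_steps + 1)
    u[0] = u0
    v[0] = v0
    w[0] = w0
    x[0] = x0
    noise = tau * epsilon * np.sqrt(D) * np.sqrt(dt)
    nterm = coef.shape[0]
    for n in range(n_steps):
        if regulator == 0:
            z = u[n]
        elif regulator == 1:
            z = v[n]
        else:
            z = w[n]
        g = 0.0
        for q in range(nterm):
            g += coef[q] * z ** powr[q]
        du = tau * (1.0 / (1.0 + w[n] ** m) - ku * u[n]) * dt
        if epsilon > 0.0:
            du += noise * np.random.standard_normal()
        u[n + 1] = u[n] + du
        v[n + 1] = v[n] + tau * (u[n] - kv * v[n]) * dt
        w[n + 1] = w[n] + tau * (v[n] - kw * w[n]) * dt
        x[n + 1] = x[n] + (alpha + beta * g - k * x[n]) * dt
    return u, v, w, x


# ---------------------------------------------------------------------------
# Frozen-path basis responses for the simulation CV evaluator
# ---------------------------------------------------------------------------

@njit(cache=True)
def theta_path(n_steps, dt, omega, epsilon, D, seed):
    """One realization of the noisy phase, unwrapped."""
    np.random.seed(seed)
    th = np.empty(n_steps + 1)
    th[0] = 0.0
    noise = epsilon * np.sqrt(D) * np.sqrt(dt)
    t = 0.0
    for n in range(n_steps):
        t += omega * dt + noise * np.random.standard_normal()
        th[n + 1] = t
    return th


@njit(cache=True)
def basis_responses(th, H, k, dt, decimate):
    """Linear-filter responses of the reporter to each Fourier drive component.

    The reporter equation is linear in the drive, so the response to
    ``alpha + beta * f(theta(t))`` is the same linear combination of the
    responses to ``cos(i theta)``, ``sin(i theta)`` and the constant drive.
    Columns: 0..2H-1 are the cos_i/sin_i responses, column 2H is the response
    to a unit constant drive.  Rows keep every ``decimate``-th step.
    """
    n_steps = th.shape[0] - 1
    n_keep = n_steps // decimate + 1
    out = np.zeros((n_keep, 2 * H + 1))
    cur = np.zeros(2 * H + 1)
    row = 1
    for n in range(n_steps):
        t = th[n]
        for i in range(1, H + 1):
            cur[2 * i - 2] += (np.cos(i * t) - k * cur[2 * i - 2]) * dt
            cur[2 * i - 1] += (np.sin(i * t) - k * cur[2 * i - 1]) * dt
        cur[2 * H] += (1.0 - k * cur[2 * H]) * dt
        if (n + 1) % decimate == 0 and row < n_keep:
            out[row] = cur
            row += 1
    return out


# ---------------------------------------------------------------------------
# Dominant-peak tracking and interval CV
# ---------------------------------------------------------------------------

@njit(cache=True)
def _local_maxima(y, i0, idx_out):
    """Indices of local maxima of y[i0:] (absolute indices). Returns count."""
    n = y.shape[0]
    cnt = 0
    for j in range(max(i0 + 1, 1), n - 1):
        if y[j] > y[j - 1] and y[j] >= y[j + 1]:
            idx_out[cnt] = j
            cnt += 1
    return cnt


@njit(cache=True)
def tracked_peak_times(y, dt, i0, tau, window, out_times, refine_half=0.0):
    """Dominant-peak marker times by sequential tracking.

    Seeds at the highest local maximum within 1.5*tau of the start, then walks
    forward: the next marker is the highest local maximum within
    ``pred +/- window`` of the predicted time ``pred = prev + tau``; if that
    band is empty the nearest maximum within ``pred +/- tau/2`` is used.

    Marker times are refined by a quadratic fit: the classic three-point
    interpolation when ``refine_half <= dt``, otherwise a least-squares
    parabola over all samples within ``refine_half`` of the marker.  The
    least-squares variant averages sampling noise near flat peaks and makes
    the refined time insensitive to the sampling interval; any waveform-shape
    bias it introduces is the same every cycle and cancels in the interval
    statistics.  Returns the marker count.
    """
    n = y.shape[0]
    idx = np.empty(n, dtype=np.int64)
    cnt = _local_maxima(y, i0, idx)
    if cnt == 0:
        return 0
    # seed marker: highest maximum in the first 1.5*tau
    t_start = i0 * dt
    best = -1
    for q in range(cnt):
        if idx[q] * dt - t_start > 1.5 * tau:
            break
        if best < 0 or y[idx[q]] > y[idx[best]]:
            best = q
    if best < 0:
        return 0
    m = 0
    cur_q = best
    cur_t = idx[best] * dt
    out_times[m] = cur_t
    m += 1
    t_end = idx[cnt - 1] * dt
    while cur_t + 1.5 * tau < t_end and m < out_times.shape[0]:
        pred = cur_t + tau
        # advance a pointer to the band [pred - window, pred + window]
        lo = cur_q
        while lo < cnt and idx[lo] * dt < pred - window:
            lo += 1
        hi = lo
        best = -1
        while hi < cnt and idx[hi] * dt <= pred + window:
            if best < 0 or y[idx[hi]] > y[idx[best]]:
                best = hi
            hi += 1
        if best < 0:
            # fall back: nearest maximum within half a period of the prediction
            lo2 = cur_q
            while lo2 < cnt and idx[lo2] * dt < pred - 0.5 * tau:
                lo2 += 1
            hi2 = lo2
            while hi2 < cnt and idx[hi2] * dt <= pred + 0.5 * tau:
                if best < 0 or abs(idx[hi2] * dt - pred) < abs(idx[best] * dt - pred):
                    best = hi2
                hi2 += 1
            if best < 0:
                # skipped beat (no detectable peak this cycle): advance the
                # prediction one period and keep tracking; the long interval
                # spanning the gap is excluded by the interval statistics
                cur_t = pred
                continue
        cur_q = best
        cur_t = idx[best] * dt
        out_times[m] = cur_t
        m += 1
    # quadratic refinement of each marker
    mw = int(refine_half / dt)
    for q in range(m):
        j = int(round(out_times[q] / dt))
        if mw <= 1:
            if 0 < j < n - 1:
                y0 = y[j - 1]
                y1 = y[j]
                y2 = y[j + 1]
                den = y0 - 2.0 * y1 + y2
                if den != 0.0:
                    d = (y0 - y2) / (2.0 * den)
                    if -1.0 < d < 1.0:
                        out_times[q] = (j + d) * dt
        else:
            lo = max(1, j - mw)
            hi = min(n - 2, j + mw)
            half = min(j - lo, hi - j)
            if half >= 1:
                # least-squares parabola on offsets -half..half
                npts = 2 * half + 1
                sy = 0.0
                sqy = 0.0
                sq2y = 0.0
                sq2 = 0.0
                sq4 = 0.0
                for o in range(-half, half + 1):
                    v = y[j + o]
                    sy += v
                    sqy += o * v
                    sq2y += o * o * v
                    sq2 += o * o
                    sq4 += o ** 4
                bcoef = sqy / sq2
                den = npts * sq4 - sq2 * sq2
                ccoef = (npts * sq2y - sq2 * sy) / den
                if ccoef < 0.0:
                    d = -bcoef / (2.0 * ccoef)
                    if d > half:
                        d = float(half)
                    elif d < -half:
                        d = float(-half)
                    out_times[q] = (j + d) * dt
    return m


@njit(cache=True)
def interval_cv(times, m, tau=0.0):
    """(cv, mean, sd, n_intervals) of successive differences of times[:m].

    With ``tau > 0``, intervals outside [0.4 tau, 1.6 tau] are excluded: such
    intervals only arise when a cycle produced no detectable marker (a
    skipped beat), and would otherwise register as a spurious double-length
    period.
    """
    if m < 3:
        return np.nan, np.nan, np.nan, 0
    n = 0
    s = 0.0
    for q in range(m - 1):
        iv = times[q + 1] - times[q]
        if tau > 0.0 and (iv < 0.4 * tau or iv > 1.6 * tau):
            continue
        s += iv
        n += 1
    if n < 2:
        return np.nan, np.nan, np.nan, 0
    mean = s / n
    ss = 0.0
    for q in range(m - 1):
        iv = times[q + 1] - times[q]
        if tau > 0.0 and (iv < 0.4 * tau or iv > 1.6 * tau):
            continue
        d = iv - mean
        ss += d * d
    sd = np.sqrt(ss / (n - 1))
    return sd / mean, mean, sd, n


@njit(cache=True)
def tracked_cv(y, dt, i0, tau, window, refine_half=0.0):
    """Peak-to-peak CV (fraction) of the dominant-peak markers of y[i0:]."""
    # markers advance by at least tau/2, so 2 periods' worth of slots suffices
    buf = np.empty(int((y.shape[0] - i0) * dt / (0.5 * tau)) + 16)
    m = tracked_peak_times(y, dt, i0, tau, window, buf, refine_half)
    cv, mean, sd, n = interval_cv(buf, m, tau)
    return cv, n


# ---------------------------------------------------------------------------
# Closed-form CV of the threshold-defined output period
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _eval_cycle(t, H, R, phi, om):
    s = 0.0
    for i in range(1, H + 1):
        s += R[i - 1] * np.sin(i * om * t + phi[i - 1])
    return s


@njit(cache=True, inline="always")
def _eval_cycle_d1(t, H, R, phi, om):
    s = 0.0
    for i in range(1, H + 1):
        s += R[i - 1] * i * om * np.cos(i * om * t + phi[i - 1])
    return s


@njit(cache=True, inline="always")
def _eval_cycle_d2(t, H, R, phi, om):
    s = 0.0
    for i in range(1, H + 1):
        s -= R[i - 1] * (i * om) ** 2 * np.sin(i * om * t + phi[i - 1])
    return s


@njit(cache=True)
def analytic_cv_kernel(c, k, om, D, epsilon, grid_m):
    """Closed-form CV (percent) for Fourier coefficients c = (A1,B1,...).

    Follows the decomposition CV = (eps/tau) * sqrt(R_TT + R_hh + 2 R_Th)
    with the checkpoint taken at the steepest upward midpoint crossing of the
    noiseless limit cycle.  Returns INF_CV for degenerate inputs so sampling
    kernels can assign them zero weight.
    """
    H = c.shape[0] // 2
    tau = TWO_PI / om
    R = np.zeros(H)
    phi = np.zeros(H)
    total = 0.0
    for i in range(1, H + 1):
        a = c[2 * i - 2]
        b = c[2 * i - 1]
        p2 = a * a + b * b
        total += p2
        R[i - 1] = np.sqrt(p2 / (k * k + (i * om) ** 2))
        if p2 > 0.0:
            den = i * om * a + k * b
            num = k * a - i * om * b
            if den > 0.0:
                phi[i - 1] = np.arctan(num / den)
            elif den < 0.0:
                phi[i - 1] = np.arctan(num / den) + np.pi
            else:
                # sgn(0) treated as +1: the correction term vanishes
                phi[i - 1] = np.pi / 2 if num >= 0.0 else -np.pi / 2
    if total < 1e-28:
        return INF_CV
    # --- limit cycle on a uniform grid via complex rotations -------------
    y = np.empty(grid_m)
    acc = np.empty(H, dtype=np.complex128)
    rot = np.empty(H, dtype=np.complex128)
    dtm = tau / grid_m
    for i in range(H):
        acc[i] = R[i] * (np.cos(phi[i]) + 1j * np.sin(phi[i]))
        ang = (i + 1) * om * dtm
        rot[i] = np.cos(ang) + 1j * np.sin(ang)
    for j in range(grid_m):
        s = 0.0
        for i in range(H):
            s += acc[i].imag
            acc[i] *= rot[i]
        y[j] = s
    # --- midpoint of the oscillation range (Newton-refined extrema) ------
    jmax = 0
    jmin = 0
    for j in range(1, grid_m):
        if y[j] > y[jmax]:
            jmax = j
        if y[j] < y[jmin]:
            jmin = j
    tmax = jmax * dtm
    tmin = jmin * dtm
    for _ in range(3):
        d2 = _eval_cycle_d2(tmax, H, R, phi, om)
        if d2 != 0.0:
            step = _eval_cycle_d1(tmax, H, R, phi, om) / d2
            if abs(step) < dtm:
                tmax -= step
    for _ in range(3):
        d2 = _eval_cycle_d2(tmin, H, R, phi, om)
        if d2 != 0.0:
            step = _eval_cycle_d1(tmin, H, R, phi, om) / d2
            if abs(step) < dtm:
                tmin -= step
    ymax = max(_eval_cycle(tmax, H, R, phi, om), y[jmax])
    ymin = min(_eval_cycle(tmin, H, R, phi, om), y[jmin])
    if ymax - ymin < 1e-14:
        return INF_CV
    mid = 0.5 * (ymax + ymin)
    # --- steepest upward midpoint crossing = checkpoint time -------------
    best_slope = -1.0
    tcp = -1.0
    for j in range(grid_m):
        j2 = j + 1 if j + 1 < grid_m else 0
        if (y[j] - mid) < 0.0 and (y[j2] - mid) >= 0.0:
            a_t = j * dtm
            b_t = (j + 1) * dtm
            # safeguarded Newton from the bracket midpoint
            tc = 0.5 * (a_t + b_t)
            for _ in range(12):
                fv = _eval_cycle(tc, H, R, phi, om) - mid
                if abs(fv) < 1e-13 or b_t - a_t < 1e-13:
                    break
                if fv < 0.0:
                    a_t = tc
                else:
                    b_t = tc
                dv = _eval_cycle_d1(tc, H, R, phi, om)
                if dv != 0.0:
                    tn = tc - fv / dv
                    if a_t < tn < b_t:
                        tc = tn
                        continue
                tc = 0.5 * (a_t + b_t)
            sl = _eval_cycle_d1(tc, H, R, phi, om)
            if sl > best_slope:
                best_slope = sl
                tcp = tc
    if tcp < 0.0 or best_slope <= 0.0:
        return INF_CV
    return cv_components_kernel(c, k, om, D, epsilon, tcp)[4] * 100.0


@njit(cache=True)
def cv_components_kernel(c, k, om, D, epsilon, tcp):
    """(R_TT, R_hh, R_Th, tcp, cv_fraction) at a given checkpoint time."""
    H = c.shape[0] // 2
    tau = TWO_PI / om
    R = np.zeros(H)
    Phi = np.zeros(H)
    for i in range(1, H + 1):
        a = c[2 * i - 2]
        b = c[2 * i - 1]
        p2 = a * a + b * b
        R[i - 1] = np.sqrt(p2 / (k * k + (i * om) ** 2))
        if p2 > 0.0:
            den = i * om * a + k * b
            num = k * a - i * om * b
            if den > 0.0:
                base = np.arctan(num / den)
            elif den < 0.0:
                base = np.arctan(num / den) + np.pi
            else:
                base = np.pi / 2 if num >= 0.0 else -np.pi / 2
            Phi[i - 1] = i * om * tcp + base
    sP = np.sin(Phi)
    cP = np.cos(Phi)
    denom = 0.0
    for i in range(1, H + 1):
        denom += i * om * R[i - 1] * cP[i - 1]
    R_tt = D * tau * tau / (TWO_PI * om)
    if denom == 0.0:
        return R_tt, np.nan, np.nan, tcp, np.nan
    decay = D * (1.0 - np.exp(-k * tau))
    R_hh = 0.0
    for i in range(1, H + 1):
        for j in range(1, H + 1):
            pref = i * j * R[i - 1] * R[j - 1]
            if pref == 0.0:
                continue
            sd = sP[i - 1] * cP[j - 1] - cP[i - 1] * sP[j - 1]
            cd = cP[i - 1] * cP[j - 1] + sP[i - 1] * sP[j - 1]
            ss = sP[i - 1] * cP[j - 1] + cP[i - 1] * sP[j - 1]
            cs = cP[i - 1] * cP[j - 1] - sP[i - 1] * sP[j - 1]
            t1 = ((i - j) * om * sd + 2.0 * k * cd) / (4.0 * k * k + (i - j) ** 2 * om * om)
            t2 = ((i + j) * om * ss + 2.0 * k * cs) / (4.0 * k * k + (i + j) ** 2 * om * om)
            R_hh += pref * (t1 + t2)
    R_hh *= decay / (denom * denom)
    R_th = 0.0
    for i in range(1, H + 1):
        if R[i - 1] == 0.0:
            continue
        R_th += i * R[i - 1] / (k * k + (i * om) ** 2) * (i * om * sP[i - 1] + k * cP[i - 1])
    R_th *= -decay / (om * denom)
    rad = R_tt + R_hh + 2.0 * R_th
    if rad < 0.0:
        return R_tt, R_hh, R_th, tcp, np.nan
    return R_tt, R_hh, R_th, tcp, (epsilon / tau) * np.sqrt(rad)


# ---------------------------------------------------------------------------
# Gibbs samplers
# ---------------------------------------------------------------------------

@njit(cache=True)
def gibbs_chain_analytic(H, k, om, D, epsilon, n_max, burn_in, grid_n,
                         seed, percent_units, grid_m):
    """Gibbs chain over Fourier coefficients with exp(-CV) weights, CV analytic.

    Coordinates x_i live on the grid -1 + 2j/grid_n, j = 0..grid_n.  One
    sample is recorded per full sweep over the 2H coordinates; the first
    ``burn_in`` sweeps are discarded.  Returns (coefficients, cv_percent).
    """
    np.random.seed(seed)
    d = 2 * H
    x = np.random.uniform(-1.0, 1.0, d)
    n_ret = n_max - burn_in
    out_c = np.empty((n_ret, d))
    out_cv = np.empty(n_ret)
    cvg = np.empty(grid_n + 1)
    w = np.empty(grid_n + 1)
    cur = analytic_cv_kernel(x, k, om, D, epsilon, grid_m)
    for s in range(n_max):
        for i in range(d):
            lo = INF_CV
            for j in range(grid_n + 1):
                x[i] = -1.0 + 2.0 * j / grid_n
                cvg[j] = analytic_cv_kernel(x, k, om, D, epsilon, grid_m)
                if cvg[j] < lo:
                    lo = cvg[j]
            if lo >= INF_CV:
                # every grid value degenerate: keep the coordinate at 0
                x[i] = 0.0
                continue
            tot = 0.0
            scale = 1.0 if percent_units else 0.01
            for j in range(grid_n + 1):
                w[j] = np.exp(-(cvg[j] - lo) * scale)
                tot += w[j]
            u = np.random.random() * tot
            acc = 0.0
            pick = grid_n
            for j in range(grid_n + 1):
                acc += w[j]
                if u <= acc:
                    pick = j
                    break
            x[i] = -1.0 + 2.0 * pick / grid_n
            cur = cvg[pick]
        if s >= burn_in:
            out_c[s - burn_in] = x
            out_cv[s - burn_in] = cur
    return out_c, out_cv


@njit(cache=True)
def combo_cv(basis, c, alpha, beta, dt_dec, i0, tau, window, refine_half, ybuf):
    """Peak-to-peak CV (percent) of x = alpha*b_const + beta*(basis @ c)."""
    n = basis.shape[0]
    d = c.shape[0]
    for r in range(n):
        s = alpha * basis[r, d]
        for q in range(d):
            s += beta * basis[r, q] * c[q]
        ybuf[r] = s
    cv, nint = tracked_cv(ybuf, dt_dec, i0, tau, window, refine_half)
    if np.isnan(cv):
        return INF_CV
    return cv * 100.0


@njit(cache=True)
def gibbs_chain_simulation(basis, alpha, beta, dt_dec, i0, tau, window,
                           refine_half, n_max, burn_in, grid_n, seed,
                           percent_units):
    """Gibbs chain with CV evaluated by simulation on a frozen noise path.

    ``basis`` holds the decimated linear-filter responses of the reporter to
    each Fourier component of the drive along one frozen realization of the
    noisy phase; every candidate coefficient vector is therefore evaluated
    under common random numbers.  Per coordinate update, the contribution of
    the unchanged coordinates is accumulated once and the grid scan only adds
    the varying column.
    """
    np.random.seed(seed)
    d = basis.shape[1] - 1
    n = basis.shape[0]
    x = np.random.uniform(-1.0, 1.0, d)
    n_ret = n_max - burn_in
    out_c = np.empty((n_ret, d))
    out_cv = np.empty(n_ret)
    cvg = np.empty(grid_n + 1)
    w = np.empty(grid_n + 1)
    ypart = np.empty(n)
    ybuf = np.empty(n)
    cur = INF_CV
    for s in range(n_max):
        for i in range(d):
            # partial combo excluding coordinate i
            for r in range(n):
                acc = alpha * basis[r, d]
                for q in range(d):
                    if q != i:
                        acc += beta * basis[r, q] * x[q]
                ypart[r] = acc
            lo = INF_CV
            for j in range(grid_n + 1):
                ci = -1.0 + 2.0 * j / grid_n
                for r in range(n):
                    ybuf[r] = ypart[r] + beta * basis[r, i] * ci
                cv, nint = tracked_cv(ybuf, dt_dec, i0, tau, window, refine_half)
                cvg[j] = INF_CV if np.isnan(cv) else cv * 100.0
                if cvg[j] < lo:
                    lo = cvg[j]
            if lo >= INF_CV:
                x[i] = 0.0
                continue
            tot = 0.0
            scale = 1.0 if percent_units else 0.01
            for j in range(grid_n + 1):
                w[j] = np.exp(-(cvg[j] - lo) * scale)
                tot += w[j]
            u = np.random.random() * tot
            acc_w = 0.0
            pick = grid_n
            for j in range(grid_n + 1):
                acc_w += w[j]
                if u <= acc_w:
                    pick = j
                    break
            x[i] = -1.0 + 2.0 * pick / grid_n
            cur = cvg[pick]
        if s >= burn_in:
            out_c[s - burn_in] = x
            out_cv[s - burn_in] = cur
    return out_c, out_cv
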