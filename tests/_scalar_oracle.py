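"""Independent straight-line scalar implementation of the ecoclimatic model.

Deliberately written as plain per-cell Python (loops, if/else, math module
only) so it shares no code path with the vectorised package implementation
it cross-checks.
"""

import math

DAYS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def month_midpoints():
    out = []
    start = 0
    for d in DAYS:
        out.append(start + d / 2.0)
        start += d
    return out


def weekly_temperature(monthly):
    """Linear cyclic interpolation of 12 month-midpoint values to 52 weeks."""
    mids = month_midpoints()
    xs = [mids[-1] - 365.0] + mids + [mids[0] + 365.0]
    ys = [monthly[-1]] + list(monthly) + [monthly[0]]
    out = []
    for w in range(52):
        day = 3.5 + 7.0 * w
        for k in range(len(xs) - 1):
            if xs[k] <= day <= xs[k + 1]:
                frac = (day - xs[k]) / (xs[k + 1] - xs[k])
                out.append(ys[k] + frac * (ys[k + 1] - ys[k]))
                break
    return out


def weekly_precip(monthly):
    out = []
    for w in range(52):
        day = 3.5 + 7.0 * w
        start = 0
        for m, d in enumerate(DAYS):
            if start <= day < start + d:
                out.append(monthly[m] * 7.0 / d)
                break
            start += d
    return out


def bucket_series(precip_w, tavg_w, capacity, evap_coeff, max_fraction,
                  tol=1e-6, max_cycles=20):
    sm = 0.5
    series = [0.0] * 52
    for _ in range(max_cycles):
        start = sm
        for w in range(52):
            evap = evap_coeff * max(0.0, tavg_w[w])
            sm = sm + (precip_w[w] - evap) / capacity
            if sm < 0.0:
                sm = 0.0
            if sm > max_fraction:
                sm = max_fraction
            series[w] = sm
        if abs(sm - start) < tol:
            break
    return series


def trapezoid(x, k0, k1, k2, k3):
    if x <= k0 or x >= k3:
        return 0.0
    if k1 <= x <= k2:
        return 1.0
    if x < k1:
        return (x - k0) / (k1 - k0)
    return (k3 - x) / (k3 - k2)


def stress(exceedances, rate):
    total = 0.0
    streak = 0
    for e in exceedances:
        if e > 0:
            streak += 1
            total += abs(rate) * e * streak
        else:
            streak = 0
    return min(total, 1.0)


def cell_ei(tmin_m, tmax_m, precip_m, params, capacity=100.0, evap_coeff=1.0,
            max_fraction=2.5):
    """EI for one cell from its 12 monthly normals; params is a dict with
    the 14 parameter codes."""
    tmin_w = weekly_temperature(tmin_m)
    tmax_w = weekly_temperature(tmax_m)
    tavg_w = [0.5 * (a + b) for a, b in zip(tmin_w, tmax_w)]
    precip_w = weekly_precip(precip_m)
    sm_w = bucket_series(precip_w, tavg_w, capacity, evap_coeff, max_fraction)

    gi_sum = 0.0
    for w in range(52):
        ti = trapezoid(tavg_w[w], params["DV0"], params["DV1"], params["DV2"], params["DV3"])
        mi = trapezoid(sm_w[w], params["SM0"], params["SM1"], params["SM2"], params["SM3"])
        gi_sum += ti * mi
    gi_a = gi_sum / 52.0

    cs = stress([max(0.0, params["TTCS"] - t) for t in tmin_w], params["THCS"])
    hs = stress([max(0.0, t - params["TTHS"]) for t in tmax_w], params["THHS"])
    ws = stress([max(0.0, s - params["SMWS"]) for s in sm_w], params["HWS"])

    return 100.0 * gi_a * (1.0 - cs) * (1.0 - hs) * (1.0 - ws)


def categorize(ei):
    if ei == 0:
        return "unsuitable"
    if ei < 10:
        return "marginal"
    if ei < 20:
        return "suitable"
    return "highly_suitable"


def sphere_cell_area(lat_deg, res_deg, radius=6371.0):
    half = res_deg / 2.0
    dlon = math.radians(res_deg)
    return radius**2 * dlon * (
        math.sin(math.radians(lat_deg + half)) - math.sin(math.radians(lat_deg - half))
    )
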