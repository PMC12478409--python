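#!/usr/bin/env python
"""Reconstruct the supplementary-only coefficient sets.

The main-text tables pin every neuro-effector curve and most gastric
constants, but defer several coefficient sets to supplementary material or
prior works: the Hai-Murphy rate constants, the Ca->MLCK kinetics, the MLIF
membrane constants, the hyperelastic polynomial, the compartment geometry
references, and the brainstem interneuron map coefficients.  This script
fixes the structural choices (documented in docs/methods.md), then solves or
fits the remaining values so the closed-loop model reproduces the reported
operating points:

  * fundic distension: lambda_f_1(V) follows the open-cylinder radius ratio
    sqrt(V/V_min) through the latch-bridge/RA_1 chain, which pins the
    kinase turnover and the intramural volume polynomials;
  * antral mechanics: the stretch excursion must saturate the occlusion
    geometry at every studied volume (hyperelastic scale);
  * PS chemosensitive control: open-state radii and mean emptying rates at
    the four studied caloric densities pin the ninth-order interneuron
    polynomial and the PS phasic stimulus duty.

Run from the repository root:  python scripts/calibrate_reconstructed.py
Rewrites src/gastroloop/_reconstructed.py.
"""

import sys
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gastroloop import compartments, mechanics, signaling  # noqa: E402
from gastroloop.params import load_registry  # noqa: E402
from gastroloop.simulator import Scenario, simulate, summarize  # noqa: E402

V_MIN, V_MAX = 0.08, 1.2
BETA_1 = 20.69
BETA_3 = 236.32
R_INI_3 = 0.2
Q3 = 0.6325                      # 1 - beta_3*b_max_3 (tonic scale)
R_MAX_3 = 0.48
Q_MAX_FLOW = 1.67

# fixed structural constants (rationale in docs/methods.md)
FIXED = {
    "k_a": 0.8, "k_b": 1.0, "k_c": 1.5,
    "km_MLCK": 1.0, "kcat_MLCP": 0.8, "km_MLCP": 1.0,
    "MLCK_cell": 2.0, "K_CaM": 0.4, "n_CaM": 4.0,
    "Ca_base": 0.10, "Ca_amp": 0.90, "V_half_Ca": -40.0, "k_Ca": 2.5,
    "R_ICC": 0.75, "R_SMC": 2.381, "tau_m_ICC": 1.5, "tau_m_SMC": 1.0,
    "Vm_rest_ICC": -67.0, "Vm_rest_SMC": -60.0,
    "t_open_frac_2": 0.45, "window_eps": 0.04, "ps_phase_lag": 0.35,
    "r_ini_1": 1.5,
    "r_ini_2": 1.65 / np.sqrt(1.1 / V_MIN),   # 1.65 cm relaxed at 1.1 L
    "L_t_2": 1.0,
    "r_ini_3": R_INI_3,
    "b_max_3": (1.0 - Q3) / BETA_3,
    "f_occ_2": 1.31 / 1.65,                   # amplitude/relaxed ratio
    "lam_on_2": 1.08, "lam_sat_2": 1.22,
    "lam_on_3": 1.03, "lam_sat_3": 1.11,
    "eta_floor": 1.0e-3,
    "f_min_mech": 0.5, "f_max_mech": 12.0, "f_mid_mech": 20.0,
    "k_inter_mech": 1.8,
    "V_tot_o": 0.5,
}

# reported operating points driving the calibration
PS_RADIUS_AT = {30.0: 0.46}       # f_chem -> open-state radius (cm)
EMPTYING_RATES = {0.33: 0.10, 0.38: 0.09, 0.50: 0.07, 0.67: 0.05}  # mL/s
R_OPEN_67 = 0.13                  # cm at g_cal = 0.67


def over_registry(over):
    o = {}
    for k, v in {**FIXED, **over}.items():
        if k in ("f_min_mech", "f_max_mech", "f_mid_mech", "k_inter_mech",
                 "k_inter_chem", "k_vol_h", "k_vol_l", "V_tot_o"):
            o[f"interneuron.{k}"] = v
        else:
            o[f"auxiliary.{k}"] = v
    return load_registry(o)


def b_ss(mlck, mlcp, reg):
    pool = mechanics.EnzymePool(mlck_act=mlck, mlck_total=mlck,
                                mlcp_f=mlcp - 7.5, mlcp_total=mlcp)
    return mechanics.total_bridges(mechanics.hai_murphy_steady_state(pool, reg))


def fundus_bridges(f_i, reg):
    sig = signaling.fundus_signals(0.0, f_i, reg)
    _, pool = compartments.fundus_enzyme_pool(sig, reg)
    return b_ss(pool.mlck_total, pool.mlcp_total, reg)


# ---------------------------------------------------------------------------
# step 1: kinase turnover + fundic reference bridge total
# ---------------------------------------------------------------------------
def step1():
    ra_max = np.sqrt(V_MAX / V_MIN)
    b_max_1 = (1.0 - ra_max ** -0.5) / BETA_1

    def resid(kcat):
        reg = over_registry({"kcat_MLCK": kcat, "b_max_1": b_max_1})
        return fundus_bridges(0.0, reg) - b_max_1

    kcat = brentq(resid, 0.02, 30.0, xtol=1e-10)
    print(f"[1] kcat_MLCK = {kcat:.6f} 1/(uM s), b_max_1 = {b_max_1:.6e}")
    return {"kcat_MLCK": kcat, "b_max_1": b_max_1}


# ---------------------------------------------------------------------------
# step 2: intramural volume polynomials
# ---------------------------------------------------------------------------
def step2(over):
    reg = over_registry(over)
    b_max_1 = over["b_max_1"]
    denom = 1.0 - BETA_1 * b_max_1

    def b_req(v):
        return max((1.0 - denom * (v / V_MIN) ** 0.25) / BETA_1, 0.0)

    def f_req(v):
        target = b_req(v)
        lo, hi = 0.0, 100.0
        b_hi = fundus_bridges(hi, reg)
        if target <= b_hi:
            return hi
        return brentq(lambda f: fundus_bridges(f, reg) - target, lo, hi,
                      xtol=1e-8)

    v_o = FIXED["V_tot_o"]
    grid_lo = np.linspace(V_MIN, v_o + 0.03, 34)
    # above ~1.12 L the required drive diverges (VIP inhibition saturates);
    # fit the smooth branch and accept polynomial extrapolation beyond it
    grid_hi = np.linspace(v_o - 0.03, 1.12, 44)
    f_lo = np.array([f_req(v) for v in grid_lo])
    f_hi = np.array([f_req(v) for v in grid_hi])

    def fit(grid, fvals, degree):
        scale = grid.max()
        u = grid / scale
        m = np.column_stack([u ** s for s in range(1, degree + 1)])
        a, *_ = np.linalg.lstsq(m, fvals, rcond=None)
        coeffs = [a[s - 1] / scale ** s for s in range(1, degree + 1)]
        resid = m @ a - fvals
        return coeffs, np.abs(resid).max()

    k_vol_h, r1 = fit(grid_lo, f_lo, 8)
    k_vol_l, r2 = fit(grid_hi, f_hi, 9)

    def peval(coeffs, v):
        return sum(k * v ** (s + 1) for s, k in enumerate(coeffs))

    jump = abs(peval(k_vol_h, v_o) - peval(k_vol_l, v_o))
    print(f"[2] k_vol fit residuals: low {r1:.2e} Hz, high {r2:.2e} Hz, "
          f"continuity jump at V_tot_o {jump:.2e} Hz")
    # verify the realized stretch against the open-cylinder target
    out = {"k_vol_h": k_vol_h, "k_vol_l": k_vol_l}
    reg2 = over_registry({**over, **out})
    for v in (0.2, 0.5, 0.6, 1.1):
        coeffs = k_vol_h if v <= v_o else k_vol_l
        b = fundus_bridges(max(peval(coeffs, v), 0.0), reg2)
        ra = ((1 - BETA_1 * b) / denom) ** 2
        ra_t = np.sqrt(v / V_MIN)
        print(f"    V={v:.2f} L: RA_1 = {ra:.4f} (target {ra_t:.4f}, "
              f"err {100 * (ra / ra_t - 1):+.2f} %)")
    return out


# ---------------------------------------------------------------------------
# step 3: hyperelastic scale
# ---------------------------------------------------------------------------
def run(over, **kw):
    reg = over_registry(over)
    sc = Scenario(**{"duration": 150.0, **kw})
    traj = simulate(sc, reg)
    return traj, reg


def antral_stats(traj, reg):
    d = traj.derived
    m = d["t_s"] >= 40.0
    dd = d.loc[m]
    lam = dd["lambda_2"].to_numpy()
    sig = dd["sigma_2_kPa"].to_numpy()
    ph = np.floor(dd["phase_2"].to_numpy()).astype(int)
    # simple per-cycle stats
    cycles = {}
    for k in np.unique(ph):
        sel = ph == k
        if sel.sum() > 5:
            cycles[k] = (lam[sel].max(), lam[sel].min(), sig[sel].max(),
                         sig[sel].min())
    ks = sorted(cycles)[1:-1]  # complete cycles only
    lam_pk = np.mean([cycles[k][0] for k in ks])
    lam_rest = np.mean([cycles[k][1] for k in ks])
    sig_pk = np.mean([cycles[k][2] for k in ks])
    sig_rest = np.mean([cycles[k][3] for k in ks])
    return lam_pk, lam_rest, sig_pk, sig_rest


def step3(over):
    # one probe run per volume: sigma does not depend on the E scale
    probe = dict(over, A_poly=[0.0, 0.0, 0.0, -45.0, 45.0])
    sig_pks, sig_rests = [], []
    for v in (0.2, 0.5, 0.6, 1.1):
        traj, reg = run(probe, mode="fixed_volume", V_tot=v, g_cal=0.0)
        lam_pk, lam_rest, s_pk, s_rest = antral_stats(traj, reg)
        sig_pks.append(s_pk)
        sig_rests.append(s_rest)
        print(f"[3] probe V={v}: lam_pk={lam_pk:.3f} lam_rest={lam_rest:.4f} "
              f"sig_pk={s_pk:.1f} sig_rest={s_rest:.3f} kPa")
    lam_target = 1.32  # comfortably above lam_sat_2 at the weakest volume
    c = min(sig_pks) / ((lam_target - 1.0) * lam_target ** 4)
    a_poly = [0.0, 0.0, 0.0, -c, c]
    print(f"[3] hyperelastic scale c = {c:.3f} kPa")
    out = dict(over, A_poly=a_poly)
    for v in (0.2, 0.6, 1.1):
        traj, reg = run(out, mode="fixed_volume", V_tot=v, g_cal=0.0)
        s = summarize(traj, reg)
        lam_pk, lam_rest, *_ = antral_stats(traj, reg)
        print(f"    V={v}: occl={s.occlusion_pct:.2f} % "
              f"relaxed={s.relaxed_antral_radius_cm:.4f} cm "
              f"amp={s.contraction_amplitude_cm:.4f} cm "
              f"lam_pk={lam_pk:.3f} lam_rest={lam_rest:.4f}")
    return {"A_poly": a_poly}


# ---------------------------------------------------------------------------
# step 4: PS chemosensitive map + phasic duty
# ---------------------------------------------------------------------------
def ps_b_req(r_open):
    return (1.0 - Q3 * np.sqrt(r_open / R_INI_3)) / BETA_3


def ps_f_i_req(r_open, reg):
    """Invert the PS tonic chain: open radius -> required NANC frequency."""
    target = ps_b_req(r_open)
    ca3 = reg.get("gastric.Ca_rest_3")
    mlck_act = mechanics.mlck_activation(ca3, reg)
    mlcp_full = reg.get("gastric.MLCP_max_3")

    def b_of_phi(phi):
        return b_ss((1 - phi) * mlck_act, 7.5 + phi * mlcp_full, reg)

    b0 = b_of_phi(0.0)
    if target >= b0:
        raise RuntimeError(
            f"PS anchor r={r_open} needs bridge total {target:.3e} >= "
            f"feasible maximum {b0:.3e}; adjust Q3/r_ini_3")
    phi = brentq(lambda p: b_of_phi(p) - target, 0.0, 0.999999, xtol=1e-10)
    curve = reg.curve("ih_to_3")
    return curve.B * (phi / (curve.A - phi)) ** (1.0 / curve.N)


def fit_chem_poly(anchors, reg):
    """Monotone interpolant through the anchors, fitted with powers 1..9."""
    pts = sorted(anchors.items())
    x = np.array([0.0] + [p[0] for p in pts])
    y = np.array([0.0] + [p[1] for p in pts])
    interp = PchipInterpolator(x, y)
    grid = np.linspace(0.0, 30.0, 400)
    vals = interp(grid)
    w = np.ones_like(grid)
    for xa in x[1:]:
        w[np.argmin(np.abs(grid - xa))] = 300.0
    u = grid / 30.0
    m = np.column_stack([u ** s for s in range(1, 10)])
    a, *_ = np.linalg.lstsq(m * w[:, None], vals * w, rcond=None)
    coeffs = [a[s - 1] / 30.0 ** s for s in range(1, 10)]

    def peval(f):
        return sum(k * f ** (s + 1) for s, k in enumerate(coeffs))

    errs = [abs(peval(xa) - anchors[xa]) for xa in anchors]
    mono = np.diff([peval(f) for f in grid[1:]])
    print(f"    chem poly: max anchor error {max(errs):.2e} Hz, "
          f"monotone: {bool((mono > -1e-9).all())}")
    return coeffs


def measure_ps(over, g_cal):
    traj, reg = run(over, mode="fixed_volume", V_tot=0.51, g_cal=g_cal,
                    duration=170.0)
    s = summarize(traj, reg)
    q_open = Q_MAX_FLOW * (s.ps_open_radius_cm / R_MAX_3) ** 2
    duty_eff = s.mean_Q_flow_mL_s / q_open if q_open > 0 else 0.0
    return s.ps_open_radius_cm, s.mean_Q_flow_mL_s, duty_eff


def step4(over):
    reg = over_registry(over)
    d_target = EMPTYING_RATES[0.67] / (Q_MAX_FLOW * (R_OPEN_67 / R_MAX_3) ** 2)
    print(f"[4] target effective open fraction D = {d_target:.4f}")

    from gastroloop.neural import chem_firing, nutrient_flow

    def f_chem_of(g):
        return chem_firing(nutrient_flow(g, reg), reg)

    # initial radius anchors assuming D = d_target for every density
    r_anchor = {f_chem_of(0.67): R_OPEN_67, 30.0: PS_RADIUS_AT[30.0]}
    for g, q in EMPTYING_RATES.items():
        if g == 0.67:
            continue
        r_anchor[f_chem_of(g)] = R_MAX_3 * np.sqrt(
            q / (d_target * Q_MAX_FLOW))
    anchors = {fc: ps_f_i_req(r, reg) for fc, r in r_anchor.items()}
    coeffs = fit_chem_poly(anchors, reg)
    cur = dict(over, k_inter_chem=coeffs)

    # tune the PS phasic stimulus duty so the realized open fraction at
    # g = 0.67 matches the target
    duty = 0.40
    for it in range(4):
        r_open, q_mean, d_eff = measure_ps(dict(cur, t_open_frac_3=duty),
                                           0.67)
        print(f"    duty={duty:.4f}: r_open={r_open:.4f} cm, "
              f"mean Q={q_mean:.4f} mL/s, D={d_eff:.4f}")
        if abs(q_mean - EMPTYING_RATES[0.67]) < 2e-4:
            break
        duty = min(max(duty + (d_eff - d_target), 0.05), 0.9)
    cur["t_open_frac_3"] = duty

    # refine the non-0.67 anchors with the realized per-density open fraction
    for _pass in range(2):
        changed = False
        for g, q_t in EMPTYING_RATES.items():
            if g == 0.67:
                continue
            fc = f_chem_of(g)
            r_open, q_mean, d_eff = measure_ps(cur, g)
            r_new = R_MAX_3 * np.sqrt(q_t / (d_eff * Q_MAX_FLOW))
            if abs(q_mean - q_t) > 5e-4:
                r_anchor[fc] = r_new
                changed = True
            print(f"    g={g}: f_chem={fc:.3f} Hz, r_open={r_open:.4f} cm, "
                  f"Q={q_mean:.4f} (target {q_t}), r_new={r_new:.4f}")
        if not changed:
            break
        anchors = {fc: ps_f_i_req(r, reg) for fc, r in r_anchor.items()}
        coeffs = fit_chem_poly(anchors, reg)
        cur["k_inter_chem"] = coeffs
    return {"k_inter_chem": cur["k_inter_chem"],
            "t_open_frac_3": cur["t_open_frac_3"]}


# ---------------------------------------------------------------------------
def write_module(over):
    path = Path(__file__).resolve().parents[1] / "src/gastroloop/_reconstructed.py"
    items = {**FIXED, **over}
    order = [
        "k_a", "k_b", "k_c", "kcat_MLCK", "km_MLCK", "kcat_MLCP", "km_MLCP",
        "MLCK_cell", "K_CaM", "n_CaM",
        "Ca_base", "Ca_amp", "V_half_Ca", "k_Ca",
        "R_ICC", "R_SMC", "tau_m_ICC", "tau_m_SMC",
        "Vm_rest_ICC", "Vm_rest_SMC",
        "t_open_frac_2", "t_open_frac_3", "window_eps", "ps_phase_lag",
        "r_ini_1", "r_ini_2", "L_t_2", "r_ini_3",
        "b_max_1", "b_max_3", "f_occ_2",
        "lam_on_2", "lam_sat_2", "lam_on_3", "lam_sat_3",
        "A_poly", "eta_floor",
        "f_min_mech", "f_max_mech", "f_mid_mech", "k_inter_mech",
        "V_tot_o", "k_inter_chem", "k_vol_h", "k_vol_l",
    ]
    lines = [
        "# Generated by scripts/calibrate_reconstructed.py -- do not edit by hand.",
        "# Coefficient sets that the primary literature reports only in supplementary",
        "# material or prior works.  Structural constants are chosen on physiological",
        "# grounds; the remaining values are solved/fitted so that the model's steady",
        "# behaviors match the reported operating points (see docs/methods.md).",
        '# Provenance for every entry here is "supplementary-reconstructed".',
        "",
        "RECONSTRUCTED = {",
    ]
    for k in order:
        v = items[k]
        if isinstance(v, (list, tuple, np.ndarray)):
            vals = ", ".join(repr(float(x)) for x in v)
            lines.append(f'    "{k}": [{vals}],')
        else:
            lines.append(f'    "{k}": {float(v)!r},')
    lines += ["}", ""]
    path.write_text("\n".join(lines))
    print(f"wrote {path}")


def main():
    over = {}
    over.update(step1())
    over.update(step2(over))
    over.update(step3(over))
    over.update(step4(over))
    write_module(over)
    # final verification with the frozen values
    print("\n=== verification (fresh registry from frozen module) ===")
    import importlib
    import gastroloop._reconstructed
    import gastroloop.params
    importlib.reload(gastroloop._reconstructed)
    importlib.reload(gastroloop.params)
    reg = gastroloop.params.load_registry()
    for name, kw in [
        ("parasym 0.6 L", dict(mode="fixed_volume", V_tot=0.6, O_sym=0)),
        ("sympath 0.6 L", dict(mode="fixed_volume", V_tot=0.6, O_sym=1)),
        ("vol 1.1 L", dict(mode="fixed_volume", V_tot=1.1, O_sym=0)),
        ("g_cal 0.67 empty", dict(mode="emptying", V_meal_0=0.3, g_cal=0.67,
                                  duration=440.0)),
    ]:
        traj = simulate(Scenario(**{"duration": 200.0, **kw}), reg)
        s = summarize(traj, reg)
        print(f"{name}: occl={s.occlusion_pct:.2f} % "
              f"relaxed={s.relaxed_antral_radius_cm:.3f} cm "
              f"amp={s.contraction_amplitude_cm:.3f} cm "
              f"ps_open={s.ps_open_radius_cm:.4f} cm "
              f"meanQ={s.mean_Q_flow_mL_s:.4f} mL/s "
              f"lam_f1={s.lambda_f_1_plateau:.4f} "
              f"cpm={s.slow_wave_cpm:.2f} wall={traj.wall_time_s:.1f} s")


if __name__ == "__main__":
    main()
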