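"""Independently coded brute-force references for the step/likelihood rules.

Everything here is written directly from the model equations, on purpose
without reusing any package internals, so that agreement with the package
is a genuine two-route check. State is a plain (q, v, n, hist) tuple of
numpy arrays / lists indexed 0..3 = A1, B, A2, C; contexts 0 = {0,1},
1 = {2,3}.
"""

import math

import numpy as np

CTX = [0, 0, 1, 1]


def fresh_state(init_q=0.0):
    return {
        "q": np.full(4, float(init_q)),
        "v": np.zeros(2),
        "n": np.ones(4),
        "hist": [[] for _ in range(4)],  # (trial_index, reward)
        "t": 0,
    }


def softmax(qc, qu, beta):
    return 1.0 / (1.0 + math.exp(min(beta * (qu - qc), 700.0)))


def step(model, st, ch, un, rc, ru, p, complete):
    """One value update, transcribed equation by equation."""
    q, v, n = st["q"], st["v"], st["n"]
    if model == "SQL":
        q[ch] = q[ch] + p["alpha1"] * (rc - q[ch])
    elif model == "SQLX":
        q[ch] = q[ch] + p["alpha1"] * (rc - q[ch])
        q[un] = q[un] + p["alpha2"] * (ru - q[un])
    elif model in ("RPD", "RPA", "RPM"):
        cf = ru if complete else q[un]
        rx = {"RPD": rc, "RPA": (rc + cf) / 2.0, "RPM": max(rc, cf)}[model]
        x = CTX[ch]
        v[x] = v[x] + p["alpha1"] * (rx - v[x])
        q[ch] = q[ch] + p["alpha2"] * ((rc - v[x]) - q[ch])
        if complete:
            q[un] = q[un] + p["alpha3"] * ((ru - v[x]) - q[un])
    elif model == "Dif":
        q[ch] = q[ch] + p["alpha1"] * ((rc - ru) - q[ch])
    elif model == "Hyb":
        cf = ru if complete else q[un]
        rhyb = p["w"] * rc + (1.0 - p["w"]) * (rc - cf)
        q[ch] = q[ch] + p["alpha1"] * (rhyb - q[ch])
    elif model == "FQL":
        q[ch] = q[ch] + p["alpha1"] * (rc - q[ch])
        q[un] = p["alpha2"] * q[un]
    elif model == "EWA":
        n_old = n[ch]
        n[ch] = p["rho"] * n_old + 1.0
        q[ch] = (q[ch] * n_old * p["phi"] + rc) / n[ch]
        if complete:
            n_old = n[un]
            n[un] = p["rho"] * n_old + 1.0
            q[un] = (q[un] * n_old * p["phi"] + p["delta_imit"] * ru) / n[un]
    elif model == "RelAsym":
        x = CTX[ch]
        v[x] = v[x] + p["alpha1"] * (rc - v[x])
        d_ch = (rc - v[x]) - q[ch]
        q[ch] = q[ch] + (p["alpha_conf"] if d_ch > 0 else p["alpha_disc"]) * d_ch
        if complete:
            d_un = (ru - v[x]) - q[un]
            q[un] = q[un] + (p["alpha_conf"] if d_un < 0 else p["alpha_disc"]) * d_un
    elif model in ("OL1", "OL2"):
        if complete:
            r = p["w"] * rc + (1.0 - p["w"]) * (rc - ru)
        else:
            r = rc
        d = r - q[ch]
        a2 = p["alpha1"] if model == "OL1" else p["alpha2"]
        q[ch] = q[ch] + p["alpha1"] * d
        q[un] = q[un] - a2 * d
    elif model == "SBE":
        st["hist"][ch].append((st["t"], rc))
        if complete:
            st["hist"][un].append((st["t"], ru))
    else:
        raise KeyError(model)
    return st


def sbe_prob(hist, t, ch, un, alpha, beta, init_q=0.0):
    """Double sum over recency-weighted sample pairs, normalised weights."""
    def wts(samples):
        if not samples:
            return [(init_q, 1.0)]
        raw = [(r, alpha * (1.0 - alpha) ** (t - i)) for i, r in samples]
        z = sum(w for _, w in raw)
        return [(r, w / z) for r, w in raw]
    total = 0.0
    for rj, wj in wts(hist[ch]):
        for rk, wk in wts(hist[un]):
            total += wj * wk * softmax(rj, rk, beta)
    return total


def replay(model, trials, p, complete, init_q=0.0):
    """Sequence NLL + final values; trials = list of (ch, un, rc, ru)."""
    st = fresh_state(init_q)
    nll = 0.0
    for ch, un, rc, ru in trials:
        st["t"] += 1
        if ch < 0:
            continue
        if model == "SBE":
            pr = sbe_prob(st["hist"], st["t"], ch, un, p["alpha1"], p["beta"], init_q)
        else:
            pr = softmax(st["q"][ch], st["q"][un], p["beta"])
        nll -= math.log(pr)
        step(model, st, ch, un, rc, ru, p, complete)
    return nll, st["q"]


def random_trials(rng, n, complete, missed_rate=0.05):
    """Random learning-phase trial tuples over the two contexts."""
    out = []
    for _ in range(n):
        ctx = rng.integers(2)
        a, b = (0, 1) if ctx == 0 else (2, 3)
        if rng.random() < missed_rate:
            out.append((-1, -1, np.nan, np.nan))
            continue
        ch, un = (a, b) if rng.random() < 0.5 else (b, a)
        rc = rng.uniform(0, 100)
        ru = rng.uniform(0, 100) if complete else np.nan
        out.append((ch, un, rc, ru))
    return out


def random_params(rng):
    return {
        "beta": rng.uniform(0, 0.3), "alpha1": rng.uniform(0, 1),
        "alpha2": rng.uniform(0, 1), "alpha3": rng.uniform(0, 1),
        "w": rng.uniform(0, 1), "rho": rng.uniform(0, 1),
        "phi": rng.uniform(0, 1), "delta_imit": rng.uniform(0, 1),
        "alpha_conf": rng.uniform(0, 1), "alpha_disc": rng.uniform(0, 1),
    }
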