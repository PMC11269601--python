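"""Independent, literal row-by-row transcription of the model equations.

Deliberately written with scalar ``math`` operations and an explicit loop
over schedule rows, so it shares no code path with the vectorized
implementation it cross-checks.
"""

import math

EPS = 0.9999999999


def oracle_predict(model: str, p: dict, schedule_rows, stot: int,
                   btot: int) -> list[float]:
    """Predicted RT per schedule row, transcribed equation by equation."""
    out = []
    for r in schedule_rows:
        S = float(r["s"])
        ST = float(r["st"])
        T = float(r["trial"])
        T_test = float(r["trial_test"])
        T_cum = float(r["trial_cum"])
        X = float(r["x"])
        tm1 = T_cum - EPS  # epsilon-substituted (T - 1)
        a, b, c, k = p["a"], p["b"], p["c"], p["k"]

        if model == "online":
            skill = a + b * math.exp(-c * S) * S ** (-k)
        elif model in ("offline_v1", "offline_v2"):
            skill = a + b * math.exp(-c * tm1) * tm1 ** (-k)
        elif model in ("offline_v1_offset", "offline_v2_offset"):
            skill = a + b * math.exp(-c * tm1) * tm1 ** (-k) - p["g"] * X
        elif model == "hybridJ":
            j = p["j"]
            sp = S * (stot - btot * j) / stot + tm1 * j
            skill = a + b * math.exp(-c * sp) * sp ** (-k)
        elif model == "hybridE":
            skill = a + b * math.exp(-c * tm1) * S ** (-k)
        elif model == "hybridP":
            skill = a + b * math.exp(-c * S) * tm1 ** (-k)
        else:
            raise ValueError(model)

        if model in ("offline_v1", "offline_v1_offset"):
            ri = 0.0
        else:
            y, z = p["y"], p["z"]
            ri = ((1 - X) * ((ST - 1) * y + (T - 1) * z)
                  + X * ((ST - 1) * y + (T_test - 1) * z))
        out.append(skill + ri)
    return out


def draw_oracle_params(model: str, rng, j_max: float) -> dict:
    """Random positive parameter draw spanning plausible magnitudes."""
    p = {
        "a": rng.uniform(500, 3000),
        "b": rng.uniform(500, 3000),
        # k capped near 0.3: the epsilon-substituted first trial scales as
        # b * 1e(10k), and beyond ~0.3 a one-ulp libm difference already
        # exceeds the 1e-9 ms comparison tolerance
        "c": 10 ** rng.uniform(-4, -1),
        "k": 10 ** rng.uniform(-3, -0.52),
        "y": rng.uniform(0.5, 40),
        "z": rng.uniform(0.5, 25),
        "g": rng.uniform(5, 300),
        "j": rng.uniform(0, j_max),
    }
    return p
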