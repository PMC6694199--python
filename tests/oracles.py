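"""Independent brute-force recomputation of trial scores.

Deliberately naive (nested loops, two-pass statistics) and written only
against the layout *table*, so it shares no code path with the package's
vectorised scoring.
"""

import math


def brute_force_scores(plant_rows, values, line_of=None):
    """Score a trial by direct enumeration.

    Parameters
    ----------
    plant_rows
        iterable of dicts with plant_id, x_m, y_m, code.
    values
        dict plant_id -> value or None (missing).
    line_of
        dict plant_id -> line id; defaults to the entry code.

    Returns
    -------
    (per_plant, per_line) dicts: plant_id -> {ring_mean, pYI, pPE} and
    line -> {mean, sd, SI, mean_pYI, sPE}.
    """
    plants = list(plant_rows)
    if line_of is None:
        line_of = {p["plant_id"]: p["code"] for p in plants}
    codes = sorted({p["code"] for p in plants})

    def dist(a, b):
        return math.hypot(a["x_m"] - b["x_m"], a["y_m"] - b["y_m"])

    per_plant = {}
    for center in plants:
        members = []
        for c in codes:
            best = None
            for q in plants:
                if q["code"] != c:
                    continue
                d = round(dist(center, q), 9)
                if best is None or d < best[0] or (d == best[0] and q["plant_id"] < best[1]):
                    best = (d, q["plant_id"])
            members.append(best[1])
        vals = [values[m] for m in members if values[m] is not None]
        ring = sum(vals) / len(vals) if vals else None
        x = values[center["plant_id"]]
        pyi = None
        if x is not None and ring is not None and ring > 0:
            pyi = (x / ring) ** 2
        per_plant[center["plant_id"]] = {"ring_mean": ring, "pYI": pyi}

    per_line = {}
    for line in sorted({line_of[p["plant_id"]] for p in plants}):
        member_ids = [
            p["plant_id"]
            for p in plants
            if line_of[p["plant_id"]] == line and values[p["plant_id"]] is not None
        ]
        xs = [values[m] for m in member_ids]
        n = len(xs)
        if n < 2:
            continue
        mean = sum(xs) / n
        var = sum((v - mean) ** 2 for v in xs) / (n - 1)
        sd = math.sqrt(var)
        si = (mean / sd) ** 2 if sd > 0 else None
        pyis = [per_plant[m]["pYI"] for m in member_ids if per_plant[m]["pYI"] is not None]
        mean_pyi = sum(pyis) / len(pyis)
        spe = si * mean_pyi if si is not None else None
        per_line[line] = {
            "mean": mean, "sd": sd, "SI": si, "mean_pYI": mean_pyi, "sPE": spe,
        }

    for p in plants:
        pid = p["plant_id"]
        line = line_of[pid]
        si = per_line.get(line, {}).get("SI")
        pyi = per_plant[pid]["pYI"]
        per_plant[pid]["pPE"] = (
            pyi * si if (pyi is not None and si is not None) else None
        )
    return per_plant, per_line
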