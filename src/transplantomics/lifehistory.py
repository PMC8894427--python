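"""Life-history rates and Leslie-matrix net reproductive rate.

Mate-pair assays give egg production rate EPR = (E_u + E_h)/t and hatching
success HS = E_h/(E_u + E_h). Survivorship beakers give day-specific
survival P_x = l_x / l_{x-1} (day 1 assumed 100%). A day-structured Leslie
matrix carries P_x on the subdiagonal and female-scaled fecundity EPR*HS*
(proportion female) on the first row from the first observed adult day on;
its dominant eigenvalue is the net reproductive rate lambda (>1 means
growth). Every eligible mate pair is crossed with every eligible beaker in a
treatment x food cell, so a cell with 4 beakers and 12 pairs yields up to 48
lambda values, summarized as mean +/- 1.960*SD/sqrt(n).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank

Z_95 = 1.960


@dataclass
class EprHs:
    epr: float | None
    hs: float | None
    epr_valid: bool
    hs_valid: bool
    reason: str = ""


def epr_and_hs(e_unhatched: int, e_hatched: int, t: float,
               male_alive: bool = True, female_alive: bool = True) -> EprHs:
    """Per-capita egg production rate and hatching success with exclusions.

    Records with a dead female are excluded entirely; a dead male still
    yields EPR but not HS; zero-egg records have EPR = 0 and undefined HS.
    """
    if e_unhatched < 0 or e_hatched < 0:
        raise ValueError("egg counts must be non-negative")
    if t <= 0:
        raise ValueError("egg-laying time must be positive")
    if not female_alive:
        return EprHs(None, None, False, False, "dead female")
    total = e_unhatched + e_hatched
    epr = total / t
    if not male_alive:
        return EprHs(epr, None, True, False, "dead male")
    if total == 0:
        return EprHs(0.0, None, True, False, "no eggs")
    return EprHs(epr, e_hatched / total, True, True)


def survivorship_probabilities(l_x) -> np.ndarray:
    """Day-specific survival P_x from counts alive l_x.

    P_1 = 1 by convention; P_x = l_x / l_{x-1}; once a beaker is extinct
    P stays 0.
    """
    l = np.asarray(l_x, dtype=float)
    if len(l) == 0 or l[0] <= 0:
        raise ValueError("need positive initial count")
    if (np.diff(l) > 0).any():
        raise ValueError("survivor counts must be non-increasing")
    p = np.ones(len(l))
    for x in range(1, len(l)):
        p[x] = l[x] / l[x - 1] if l[x - 1] > 0 else 0.0
    return p


def assemble_leslie(p_x, epr: float, hs: float, n_females: int, n_males: int,
                    maturity_day: int, strict_after: bool = False) -> np.ndarray:
    """Day-structured Leslie matrix from survival and fecundity.

    ``p_x`` holds P_1..P_d on the observation grid. The first row gets
    F = EPR * HS * (females / (females + males)) on every day >=
    ``maturity_day`` (1-based; > with ``strict_after``); the subdiagonal
    carries P_2..P_d.
    """
    p = np.asarray(p_x, dtype=float)
    d = len(p)
    if not 1 <= maturity_day <= d:
        raise ValueError("maturity_day outside the observation series")
    if n_females + n_males == 0:
        raise ValueError("no sexed adults: cannot scale fecundity")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("survival probabilities must be in [0, 1]")
    f = epr * hs * (n_females / (n_females + n_males))
    m = np.zeros((d, d))
    first = maturity_day + 1 if strict_after else maturity_day
    m[0, first - 1:] = f
    for i in range(1, d):
        m[i, i - 1] = p[i]
    return m


def dominant_eigenvalue(matrix: np.ndarray) -> float:
    """Perron root: magnitude of the largest-modulus eigenvalue."""
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("Leslie matrix must be non-negative")
    if not m.any():
        return 0.0
    return float(np.abs(np.linalg.eigvals(m)).max())


def _beaker_series(surv: pd.DataFrame) -> list[dict]:
    out = []
    for bid, grp in surv.sort_values("day").groupby("beaker_id"):
        out.append({
            "beaker_id": bid,
            "treatment": grp["treatment"].iloc[0],
            "food": grp["food"].iloc[0],
            "l": grp["alive"].to_numpy(),
            "days": grp["day"].to_numpy(),
            "n_females": int(grp["n_females"].iloc[0]),
            "n_males": int(grp["n_males"].iloc[0]),
            "first_adult_day": int(grp["first_adult_day"].iloc[0]),
        })
    return out


def lambda_ensemble(survivorship: pd.DataFrame, matepairs: pd.DataFrame) -> pd.DataFrame:
    """Cross every eligible beaker with every eligible mate pair per cell.

    Eligible beakers have sexed adults; eligible pairs have a live female
    and a defined fecundity (live male, or zero eggs giving F = 0). Returns
    one row per treatment x food with lambda mean, SD, n and the normal 95%
    CI; cells with no eligible combination are flagged.
    """
    rows = []
    beakers = _beaker_series(survivorship)
    for (treatment, food), pair_grp in matepairs.groupby(["treatment", "food"]):
        cell_beakers = [b for b in beakers
                        if b["treatment"] == treatment and b["food"] == food
                        and b["n_females"] + b["n_males"] > 0
                        and b["n_females"] > 0]
        fecundities = []
        for _, r in pair_grp.iterrows():
            res = epr_and_hs(r["e_unhatched"], r["e_hatched"], r["days"],
                             bool(r["male_alive"]), bool(r["female_alive"]))
            if not res.epr_valid:
                continue
            if res.hs_valid:
                fecundities.append(res.epr * res.hs)
            elif res.epr == 0:
                fecundities.append(0.0)  # zero eggs: fecundity zero, HS moot
        lambdas = []
        for b in cell_beakers:
            p = survivorship_probabilities(b["l"])
            # survival beyond extinction or with zero fecundity still yields
            # a matrix; maturity day mapped onto the observation grid
            day_index = int(np.searchsorted(b["days"], b["first_adult_day"])) + 1
            day_index = min(max(day_index, 1), len(p))
            for f in fecundities:
                # f = EPR*HS; assemble_leslie applies the sex-ratio scaling
                m = assemble_leslie(p, f, 1.0, b["n_females"], b["n_males"],
                                    day_index)
                lambdas.append(dominant_eigenvalue(m))
        if not lambdas:
            rows.append({"treatment": treatment, "food": food, "n": 0,
                         "lambda_mean": np.nan, "sd": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "missing": True})
            continue
        lam = np.asarray(lambdas)
        mean = lam.mean()
        sd = lam.std(ddof=1) if len(lam) > 1 else 0.0
        half = Z_95 * sd / np.sqrt(len(lam))
        rows.append({"treatment": treatment, "food": food, "n": len(lam),
                     "lambda_mean": float(mean), "sd": float(sd),
                     "ci_low": float(mean - half), "ci_high": float(mean + half),
                     "missing": False})
    return pd.DataFrame(rows)


def _events_from_series(surv: pd.DataFrame):
    """Per-individual event times (death day, observed) from l_x decrements;
    survivors at the last observation are right-censored."""
    times, events = [], []
    for _, b in surv.sort_values("day").groupby("beaker_id"):
        l = b["alive"].to_numpy()
        days = b["day"].to_numpy()
        for prev, cur, day in zip(l[:-1], l[1:], days[1:]):
            deaths = int(prev - cur)
            times += [day] * deaths
            events += [1] * deaths
        times += [int(days[-1])] * int(l[-1])
        events += [0] * int(l[-1])
    return np.asarray(times), np.asarray(events)


def logrank_test(series_group1: pd.DataFrame, series_group2: pd.DataFrame) -> dict:
    """Two-group log-rank comparison of survivorship curves."""
    t1, e1 = _events_from_series(series_group1)
    t2, e2 = _events_from_series(series_group2)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("empty survivorship group")
    if e1.sum() + e2.sum() == 0:
        return {"statistic": 0.0, "p": 1.0}
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}
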