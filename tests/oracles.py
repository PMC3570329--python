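"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive — day-by-day scans, closed forms,
hand-rolled contingency arithmetic — and shares no code with the
implementation under test.
"""

from __future__ import annotations

from collections import defaultdict

WINDOW = 365
GRACE = 60
HORIZON = WINDOW - 1  # analysis confined to the window


def mpr_days_sum_oracle(fills: list[tuple[int, int]]) -> int:
    """Classic MPR numerator: sum of supplies truncated at the window end, capped."""
    total = sum(min(s, WINDOW - t) for t, s in fills if 0 <= t < WINDOW)
    return min(WINDOW, total)


def mpr_days_coverage_oracle(fills: list[tuple[int, int]]) -> int:
    """Day-by-day stock simulation: one day of supply consumed per covered day."""
    arriving = defaultdict(int)
    for t, s in fills:
        if 0 <= t < WINDOW:
            arriving[t] += s
    stock = 0
    covered = 0
    for day in range(WINDOW):
        stock += arriving[day]
        if stock > 0:
            covered += 1
            stock -= 1
    return covered


def episode_oracle(
    index_fills: list[tuple[int, int]],
    other_fill_days: list[int],
    grace: int = GRACE,
    any_asa_closes_gap: bool = True,
) -> tuple[str, int]:
    """Exhaustive day-scan classification: (event_type, event_time_days).

    Simulates index-product stock day by day over the observable horizon,
    finds every runout followed by a silent period of >= ``grace`` days,
    and applies the switch-beats-later-gap rule.
    """
    arriving = defaultdict(int)
    idx_days = set()
    for t, s in index_fills:
        if 0 <= t <= HORIZON:
            arriving[t] += s
            idx_days.add(t)
    other_days = sorted(d for d in other_fill_days if 0 <= d <= HORIZON)

    covered = []
    stock = 0
    for day in range(HORIZON + 1):
        stock += arriving[day]
        if stock > 0:
            covered.append(True)
            stock -= 1
        else:
            covered.append(False)

    switch_day = next((d for d in other_days if d < WINDOW), None)

    gap_event = None
    for d in range(1, HORIZON + 1):
        if covered[d] or not covered[d - 1]:
            continue  # not a runout boundary
        silent = range(d, d + grace)
        if silent[-1] > HORIZON:
            continue  # grace period does not elapse inside the window
        if any(day in idx_days for day in silent):
            continue
        if any_asa_closes_gap and any(day in silent for day in other_days):
            continue
        gap_event = d
        break

    if switch_day is not None and (gap_event is None or switch_day < gap_event):
        return "SWITCH", max(1, switch_day)
    if gap_event is not None:
        return "GAP_DISCONTINUATION", gap_event
    return "CENSORED", WINDOW


def or_2x2(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio for exposed (a of a+b) vs unexposed (c of c+d)."""
    return (a * d) / (b * c)


def chisq_k_by_2(successes, totals) -> float:
    """Textbook Pearson chi-square on a k x 2 table, from expected counts."""
    grand = sum(totals)
    succ = sum(successes)
    stat = 0.0
    for s, t in zip(successes, totals):
        for obs, margin in ((s, succ), (t - s, grand - succ)):
            exp = t * margin / grand
            stat += (obs - exp) ** 2 / exp
    return stat


def logrank_oracle(groups: dict) -> float:
    """Observed-minus-expected log-rank chi-square for two groups.

    ``groups`` maps label -> list of (time, observed_bool).  Standard
    hypergeometric variance form, computed from first principles.
    """
    labels = list(groups)
    assert len(labels) == 2
    times = sorted({t for eps in groups.values() for t, obs in eps if obs})
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_at_risk = {g: sum(1 for tt, _ in eps if tt >= t) for g, eps in groups.items()}
        d = {g: sum(1 for tt, obs in eps if tt == t and obs) for g, eps in groups.items()}
        n_tot = sum(n_at_risk.values())
        d_tot = sum(d.values())
        if n_tot < 2 or d_tot == 0:
            continue
        g0 = labels[0]
        expected = d_tot * n_at_risk[g0] / n_tot
        o_minus_e += d[g0] - expected
        var += (
            d_tot
            * (n_at_risk[g0] / n_tot)
            * (1 - n_at_risk[g0] / n_tot)
            * (n_tot - d_tot)
            / (n_tot - 1)
        )
    return o_minus_e**2 / var


def km_survival_oracle(episodes: list[tuple[int, bool]], at: float) -> float:
    """Hand product-limit estimate S(at) from (time, observed) pairs."""
    s = 1.0
    for t in sorted({t for t, obs in episodes if obs}):
        if t > at:
            break
        n = sum(1 for tt, _ in episodes if tt >= t)
        d = sum(1 for tt, obs in episodes if tt == t and obs)
        s *= 1 - d / n
    return s


def cds_oracle(code_classes: list[str | None], points: dict, combos=()) -> int:
    """Enumerate distinct classes from scratch and sum weights + combo deltas."""
    classes = {c for c in code_classes if c is not None}
    total = sum(points.get(c, 0) for c in classes)
    for combo, delta in combos:
        if set(combo) <= classes:
            total += delta
    return total
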