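"""Independent brute-force oracles used only by the test suite.

Straight-line transcriptions of the defining formulas, kept deliberately
naive (python loops, no shared code with the implementation) so they can
serve as an independent cross-check.
"""


def is_bruteforce(x, p=24):
    """Interdaily stability from its defining ratio, by direct loops."""
    n = len(x)
    d = n // p
    xbar = sum(x) / n
    hour_means = []
    for h in range(p):
        vals = [x[day * p + h] for day in range(d)]
        hour_means.append(sum(vals) / d)
    num = n * sum((xh - xbar) ** 2 for xh in hour_means)
    den = p * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def iv_bruteforce(x):
    """Intradaily variability from its defining ratio, by direct loops."""
    n = len(x)
    xbar = sum(x) / n
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def window_scan_bruteforce(minute_means, length, mode):
    """Naive O(1440·L) circular window scan; earliest-start tie-break.

    Each window is summed from scratch over a doubled copy of the
    profile (no prefix sums, no shared code with the implementation).
    """
    n = len(minute_means)
    doubled = list(minute_means) + list(minute_means)
    # windows tied up to summation rounding count as equal (earliest wins)
    tol = 1e-9 * max((abs(v) for v in minute_means), default=0.0)
    best_level = None
    best_start = None
    for start in range(n):
        level = sum(doubled[start : start + length]) / length
        better = (
            best_level is None
            or (mode == "max" and level > best_level + tol)
            or (mode == "min" and level < best_level - tol)
        )
        if better:
            best_level, best_start = level, start
    return best_level, best_start
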