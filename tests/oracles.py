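"""Independent brute-force checkers used as oracles by the test suite.

Everything here is written directly from the rule definitions with plain
Python loops, deliberately sharing no code with the package engines.
"""

from __future__ import annotations

from math import comb


def brute_westgard(z: list[float]) -> list[tuple[str, tuple[int, ...]]]:
    """All (rule_id, indices) firings of the default Westgard set on ``z``.

    Definitions checked point by point:
      1_2s: |z_i| > 2;  1_3s: |z_i| > 3
      2_2s: z_{i-1}, z_i both > 2 or both < -2
      R_4s: z_{i-1}, z_i opposite signs and |z_i - z_{i-1}| >= 4
      4_1s: 4 consecutive all > 1 or all < -1
      10_x: 10 consecutive all > 0 or all < 0
    """
    fired: list[tuple[str, tuple[int, ...]]] = []
    n = len(z)
    for i in range(n):
        if abs(z[i]) > 2:
            fired.append(("1_2s", (i,)))
        if abs(z[i]) > 3:
            fired.append(("1_3s", (i,)))
    for i in range(1, n):
        a, b = z[i - 1], z[i]
        if (a > 2 and b > 2) or (a < -2 and b < -2):
            fired.append(("2_2s", (i - 1, i)))
        if ((a > 0 and b < 0) or (a < 0 and b > 0)) and abs(b - a) >= 4:
            fired.append(("R_4s", (i - 1, i)))
    for i in range(n - 3):
        w = z[i : i + 4]
        if all(v > 1 for v in w) or all(v < -1 for v in w):
            fired.append(("4_1s", tuple(range(i, i + 4))))
    for i in range(n - 9):
        w = z[i : i + 10]
        if all(v > 0 for v in w) or all(v < 0 for v in w):
            fired.append(("10_x", tuple(range(i, i + 10))))
    fired.sort(key=lambda t: (t[1][0], t[1][-1], t[0]))
    return fired


def brute_eqa_rules(
    pds: list[float],
    sdis: list[float],
    tea: float,
    *,
    min_same_side: int = 5,
) -> list[tuple[str, tuple[int, ...]]]:
    """All EQA multirule firings on a date-ordered series.

    Definitions checked directly:
      1_TEa: |pd_i| > TEa;  1_75pTEa: |pd_i| > 0.75 * TEa
      same_side: series length >= min_same_side and every pd on one side
      2of3_2SDI: within any 3 consecutive events, >= 2 have SDI > 2
                 (or >= 2 have SDI < -2); indices are the offending events
      R_range: max(SDI) - min(SDI) > 4; indices are the extreme events
    """
    fired: list[tuple[str, tuple[int, ...]]] = []
    n = len(pds)
    for i in range(n):
        if abs(pds[i]) > tea:
            fired.append(("1_TEa", (i,)))
        if abs(pds[i]) > 0.75 * tea:
            fired.append(("1_75pTEa", (i,)))
    if n >= min_same_side and (all(p > 0 for p in pds) or all(p < 0 for p in pds)):
        fired.append(("same_side", tuple(range(n))))
    seen = set()
    for i in range(n - 2):
        for sign in (1, -1):
            hits = tuple(j for j in range(i, i + 3) if sign * sdis[j] > 2)
            if len(hits) >= 2 and ("2of3_2SDI", hits) not in seen:
                seen.add(("2of3_2SDI", hits))
                fired.append(("2of3_2SDI", hits))
    if n >= 2 and max(sdis) - min(sdis) > 4:
        lo = min(range(n), key=lambda j: sdis[j])
        hi = max(range(n), key=lambda j: sdis[j])
        fired.append(("R_range", tuple(sorted((lo, hi)))))
    fired.sort(key=lambda t: (t[1][0], t[1][-1], t[0]))
    return fired


def fisher_two_sided(n1: int, x1: int, n2: int, x2: int) -> float:
    """Fisher exact p by hypergeometric enumeration.

    Fixing all margins, the count in cell (1,1) is hypergeometric; the
    two-sided p-value sums the probabilities of all tables at most as
    probable as the observed one.
    """
    total = n1 + n2
    successes = x1 + x2
    denom = comb(total, successes)

    def prob(k: int) -> float:
        if k < 0 or k > n1 or successes - k > n2 or successes - k < 0:
            return 0.0
        return comb(n1, k) * comb(n2, successes - k) / denom

    p_obs = prob(x1)
    return sum(
        p for k in range(successes + 1)
        if (p := prob(k)) <= p_obs * (1 + 1e-9)
    )


def yates_chi2(x1: int, n1: int, x2: int, n2: int) -> float:
    """Continuity-corrected chi-square statistic for a 2x2 table,
    N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n = a + b + c + d
    num = n * (max(abs(a * d - b * c) - n / 2.0, 0.0)) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den
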