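"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (textbook
formulas, explicit enumeration, direct interpretation) and shares no code
with the implementation under test.
"""

from __future__ import annotations

import math
from itertools import product


def interpret_delegate(space, start, s1, switch, s2, others_rounds, rounds=10):
    """Directly interpret a delegate program against scripted opponents.

    ``others_rounds[r]`` is the list of the three opponents' contributions
    in round r (0-based).  Returns the agent's own contribution sequence.
    The public account accumulates the agent's and the opponents' moves;
    the strategy switch is evaluated against the account before the round.
    """
    space = list(space)

    def nearest_up(x):
        best, bd = None, None
        for a in space:
            d = abs(x - a)
            if bd is None or d < bd or (d == bd and a > best):
                best, bd = a, d
        return best

    actions = []
    account = 0
    for r in range(rounds):
        if r == 0:
            a = start
        else:
            strat = s2 if account >= switch else s1
            avg = sum(others_rounds[r - 1]) / len(others_rounds[r - 1])
            a = strat[space.index(nearest_up(avg))]
        actions.append(a)
        account += a + sum(others_rounds[r])
    return actions


def welch_formula(a, b):
    """Welch t statistic and Satterthwaite df, straight from the textbook."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def fisher_two_sided(table):
    """Two-sided Fisher exact p by full enumeration over the margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def comb(n_, k_):
        return math.comb(n_, k_)

    def prob(x):  # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def balanced_anova_ss(cells):
    """Closed-form sums of squares for a balanced 2x2 ANOVA.

    ``cells[(i, j)]`` is the list of observations in factor-A level i,
    factor-B level j (i, j in {0, 1}), all of equal size n.  Returns
    (ss_a, ss_b, ss_ab, ss_error).
    """
    n = len(cells[(0, 0)])
    means = {ij: sum(v) / n for ij, v in cells.items()}
    grand = sum(means.values()) / 4
    a_means = {i: (means[(i, 0)] + means[(i, 1)]) / 2 for i in (0, 1)}
    b_means = {j: (means[(0, j)] + means[(1, j)]) / 2 for j in (0, 1)}
    ss_a = 2 * n * sum((a_means[i] - grand) ** 2 for i in (0, 1))
    ss_b = 2 * n * sum((b_means[j] - grand) ** 2 for j in (0, 1))
    ss_ab = n * sum(
        (means[(i, j)] - a_means[i] - b_means[j] + grand) ** 2
        for i in (0, 1)
        for j in (0, 1)
    )
    ss_err = sum(
        (x - means[(i, j)]) ** 2 for (i, j), v in cells.items() for x in v
    )
    return ss_a, ss_b, ss_ab, ss_err


def all_three_choice_tables():
    """Every (start, strategy1, strategy2) program over the space (0, 2, 4)."""
    space = (0, 2, 4)
    for start in space:
        for s1 in product(space, repeat=3):
            for s2 in product(space, repeat=3):
                yield start, s1, s2
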