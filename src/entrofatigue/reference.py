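"""Naive double-loop reference implementations of the template entropies.

These are deliberately literal transcriptions of the textbook definitions —
explicit loops over template pairs, no vectorization — kept independent of
:mod:`entrofatigue.entropy` so they can serve as oracles in tests.  O(N^2)
in pure Python: use only on short series.
"""

from __future__ import annotations

import math


def _sd(x: list[float]) -> float:
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / n)


def _chebyshev(a: list[float], b: list[float]) -> float:
    return max(abs(u - v) for u, v in zip(a, b))


def naive_approximate_entropy(x, m: int = 2, r_factor: float = 0.2) -> float:
    x = [float(v) for v in x]
    n = len(x)
    r = r_factor * _sd(x)
    if r <= 0:
        raise ValueError("zero-variance series")

    def phi(mm: int) -> float:
        count = n - mm + 1
        templates = [x[i:i + mm] for i in range(count)]
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):  # includes j == i
                if _chebyshev(templates[i], templates[j]) <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def naive_sample_entropy(x, m: int = 2, r_factor: float = 0.2) -> float:
    x = [float(v) for v in x]
    n = len(x)
    r = r_factor * _sd(x)
    if r <= 0:
        raise ValueError("zero-variance series")
    count = n - m
    t_m = [x[i:i + m] for i in range(count)]
    t_m1 = [x[i:i + m + 1] for i in range(count)]
    b = a = 0
    for i in range(count):
        for j in range(i + 1, count):
            if _chebyshev(t_m[i], t_m[j]) <= r:
                b += 1
            if _chebyshev(t_m1[i], t_m1[j]) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def naive_fuzzy_entropy(x, m: int = 2, r_factor: float = 0.2, n_grad: float = 2.0) -> float:
    x = [float(v) for v in x]
    n = len(x)
    r = r_factor * _sd(x)
    if r <= 0:
        raise ValueError("zero-variance series")
    count = n - m

    def phi(mm: int) -> float:
        templates = []
        for i in range(count):
            seg = x[i:i + mm]
            mean = sum(seg) / mm
            templates.append([v - mean for v in seg])
        total = 0.0
        for i in range(count):
            for j in range(count):
                if i == j:
                    continue
                d = _chebyshev(templates[i], templates[j])
                total += math.exp(-((d / r) ** n_grad))
        return total / (count * (count - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def naive_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit concordant-pair counting (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
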