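"""Independent numerical oracles used by the test suite."""


def bisect_bound_ligand(p: float, l: float, kd: float, tol: float = 1e-16) -> float:
    """Bound-ligand concentration from 1:1 mass balance, by bisection.

    Solves (P - B)(L - B) = Kd * B for B in [0, min(P, L)] using only sign
    tests on g(B) = (P - B)(L - B) - Kd * B; deliberately independent of the
    closed-form quadratic it cross-checks.
    """
    lo, hi = 0.0, min(p, l)
    if kd == 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (p - mid) * (l - mid) - kd * mid > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-30):
            break
    return 0.5 * (lo + hi)
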