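"""Exact symbolic first-order growth derivative (independent test oracle).

Re-derives lambda' = d(lambda)/dw at w = 0 with sympy rationals, straight
from the model definition and independently of the package's numerics:
the projection matrix is expanded as Q = Q0 + w Q1(x) with lambda = 1 + w x
(under the neutral time profile e^{-duration} is rational at w = 0, so Q0
is an exact rational matrix), and the secular condition

    det(Q0 + w Q1 - I) = det(Q0 - I) + w tr(adj(Q0 - I) Q1) + O(w^2) = 0

is solved for x — the first-order coefficient is linear in x.  Exponential
in M; intended for small life cycles only.
"""

import math

import sympy as sp


def lambda_prime_symbolic(parts, a, b, c, d, m):
    """Exact lambda' for the life cycle ``parts`` under game (a,b,c,d).

    Returns (det(Q0 - I), lambda') as sympy expressions; the determinant
    must be 0 (the neutral landscape) for the result to be meaningful.
    """
    M = sum(parts)
    a, b, c, d, m = map(sp.Rational, (a, b, c, d, m))
    x = sp.symbols("x")

    def payoffs(i, j):
        if i + j == 1:
            return sp.Integer(0), sp.Integer(0)
        return (((i - 1) * a + j * b) / sp.Integer(i + j - 1),
                (i * c + (j - 1) * d) / sp.Integer(i + j - 1))

    sizes = sorted(set(parts))
    types = [(s, na) for s in sizes for na in range(s, -1, -1)]
    S = len(types)

    def frag(i):
        vec = [sp.Integer(0)] * S
        for s in parts:
            for xa in range(max(0, s - (M - i)), min(s, i) + 1):
                vec[types.index((s, xa))] += sp.Rational(
                    math.comb(i, xa) * math.comb(M - i, s - xa), math.comb(M, s))
        return vec

    Q0 = sp.zeros(S, S)
    Q1 = sp.zeros(S, S)
    keep2, mix, switch2 = (1 - m) ** 2, 2 * m * (1 - m), m ** 2
    for k, (s, na) in enumerate(types):
        # stack entries: composition, probability to orders 0/1 in w,
        # R = prod (n+1)/n over sizes passed (e^{-duration} = 1/R at w=0),
        # D1 = first-order duration correction
        stack = [((na, s - na), sp.Integer(1), sp.Integer(0),
                  sp.Rational(1), sp.Integer(0))]
        while stack:
            (i, j), p0, p1, R, D1 = stack.pop()
            if i + j == M:
                corr = x * sp.log(R) + D1
                for jj, Nj in enumerate(frag(i)):
                    if Nj:
                        Q0[k, jj] += p0 * Nj / R
                        Q1[k, jj] += Nj * (p1 - p0 * corr) / R
                continue
            al, be = payoffs(i, j)
            n = i + j
            Tn = sp.log(sp.Rational(n + 1, n))
            avg = (i * al + j * be) / sp.Integer(n)
            pa0 = sp.Rational(i, n)
            pa1 = sp.Rational(i * j, n ** 2) * (al - be)
            pb0, pb1 = 1 - pa0, -pa1
            steps: dict = {}

            def add(t, q0, q1):
                o = steps.get(t, (sp.Integer(0), sp.Integer(0)))
                steps[t] = (o[0] + q0, o[1] + q1)

            add((i + 1, j), pa0 * keep2, pa1 * keep2)
            add((i, j + 1), pa0 * mix, pa1 * mix)
            add((i - 1, j + 2), pa0 * switch2, pa1 * switch2)
            add((i, j + 1), pb0 * keep2, pb1 * keep2)
            add((i + 1, j), pb0 * mix, pb1 * mix)
            add((i + 2, j - 1), pb0 * switch2, pb1 * switch2)
            for (ti, tj), (q0, q1) in steps.items():
                if ti < 0 or tj < 0 or (q0 == 0 and q1 == 0):
                    continue
                stack.append(((ti, tj), p0 * q0, p0 * q1 + p1 * q0,
                              R * sp.Rational(n + 1, n), D1 - Tn * avg))

    A = Q0 - sp.eye(S)
    det0 = sp.simplify(A.det())
    secular = sp.expand((A.adjugate() * Q1).trace())
    slope = -secular.coeff(x, 0) / secular.coeff(x, 1)
    return det0, slope
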