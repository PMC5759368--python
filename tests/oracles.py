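"""Independent reference implementations used only by the test suite.

Each oracle is a direct, unoptimised transcription of the relevant verbal
definition or published formula, deliberately sharing no code with the
package internals it checks.
"""

import numpy as np
from scipy.linalg import expm


def classify_site(p1: str, p2: str, p3: str, p4: str) -> str:
    """Literal per-site rule: ABBA when P2 and P3 share an allele while P1
    and P4 share a different one; BABA when P1 and P3 share an allele while
    P2 and P4 share a different one; anything else is neither."""
    site = (p1, p2, p3, p4)
    if any(ch not in "ACGT" for ch in site):
        return "missing"
    if p2 == p3 and p1 == p4 and p1 != p2:
        return "ABBA"
    if p1 == p3 and p2 == p4 and p1 != p2:
        return "BABA"
    return "other"


def count_patterns_bruteforce(seqs: dict[str, str],
                              quartet: tuple[str, str, str, str]
                              ) -> tuple[int, int]:
    s1, s2, s3, s4 = (seqs[lab] for lab in quartet)
    n_abba = n_baba = 0
    for a, b, c, d in zip(s1, s2, s3, s4):
        cls = classify_site(a, b, c, d)
        if cls == "ABBA":
            n_abba += 1
        elif cls == "BABA":
            n_baba += 1
    return n_abba, n_baba


def jackknife_bruteforce(num_blocks, den_blocks):
    """Delete-m(j) weighted jackknife written out long-hand.

    Weights m_j are the block denominators; h_j = n / m_j.  Returns
    (estimate, SE, Z) with SE = sqrt(var); var can be negative when some
    weights are negative, in which case SE and Z are NaN.
    """
    num = [float(x) for x in num_blocks]
    den = [float(x) for x in den_blocks]
    g = len(num)
    n = sum(den)
    theta = sum(num) / n
    theta_del = []
    for j in range(g):
        s = sum(num[i] for i in range(g) if i != j)
        w = sum(den[i] for i in range(g) if i != j)
        theta_del.append(s / w)
    theta_dot = g * theta - sum((1 - den[j] / n) * theta_del[j]
                                for j in range(g))
    var = 0.0
    for j in range(g):
        h = n / den[j]
        pseudo = h * theta - (h - 1) * theta_del[j]
        var += (pseudo - theta_dot) ** 2 / (h - 1)
    var /= g
    if var < 0:
        return theta, float("nan"), float("nan")
    se = var ** 0.5
    return theta, se, theta / se if se > 0 else float("nan")


def hky_q(kappa: float, gc: float) -> tuple[np.ndarray, np.ndarray]:
    """HKY rate matrix (A,C,G,T order) normalised to mean rate 1, with its
    stationary distribution; built independently of the package."""
    at = (1 - gc) / 2
    pi = np.array([at, gc / 2, gc / 2, at])
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        q[i, i] = -q[i].sum()
    q /= -(pi * np.diag(q)).sum()
    return q, pi


def hky_gamma_pdiff(t: float, kappa: float = 3.6, gc: float = 0.40,
                    alpha: float = 1.0, n_nodes: int = 60) -> float:
    """Expected proportion of differing sites between two sequences at
    total distance ``t`` under HKY with Gamma(alpha, mean 1) site rates.

    Integrates the matrix exponential over the rate density with
    Gauss-Laguerre quadrature (generalised for alpha via the weight
    r^(alpha-1) e^(-alpha r))."""
    q, pi = hky_q(kappa, gc)
    nodes, weights = np.polynomial.laguerre.laggauss(n_nodes)
    # integral of f(r) alpha^alpha r^(a-1) e^(-alpha r)/Gamma(a) dr with
    # substitution x = alpha * r
    from math import gamma as gamma_fn
    p_same = 0.0
    norm = 0.0
    for x, w in zip(nodes, weights):
        r = x / alpha
        dens = x ** (alpha - 1.0)
        p = expm(q * (r * t))
        p_same += w * dens * float((pi * np.diag(p)).sum())
        norm += w * dens
    p_same /= norm
    assert abs(norm - gamma_fn(alpha)) < 1e-6 * max(1.0, gamma_fn(alpha))
    return 1.0 - p_same
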