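"""Independent brute-force transcription of the segregation-index formula.

Deliberately written as literal nested sums over points and permutations,
with no shared code with viscmap.spatial, so it can serve as an oracle.
"""

from math import dist


def si_bruteforce(X, Y, perms):
    """Segregation index of X against Y under the given label permutations.

    X, Y: sequences of coordinate tuples; perms: sequence of permutations of
    range(n + m).
    """
    X = [tuple(p) for p in X]
    Y = [tuple(p) for p in Y]
    n, m = len(X), len(Y)
    Z = X + Y

    num = 0.0
    for i in range(n):
        cross = sum(dist(X[i], Y[k]) for k in range(m)) / m
        own = sum(dist(X[i], X[j]) for j in range(n) if j != i) / (n - 1)
        num += cross - own
    for k in range(m):
        cross = sum(dist(Y[k], X[i]) for i in range(n)) / n
        own = sum(dist(Y[k], Y[l]) for l in range(m) if l != k) / (m - 1)
        num += cross - own
    num /= n + m

    den = 0.0
    for sigma in perms:
        s = 0.0
        for i in range(n):
            zi = Z[sigma[i]]
            s += sum(dist(zi, Z[sigma[n + k]]) for k in range(m)) / m
            s += sum(dist(zi, Z[sigma[j]]) for j in range(n) if j != i) / (n - 1)
        for k in range(m):
            zk = Z[sigma[n + k]]
            s += sum(dist(zk, Z[sigma[i]]) for i in range(n)) / n
            s += sum(dist(zk, Z[sigma[n + l]]) for l in range(m) if l != k) / (m - 1)
        den += s / (2 * (n + m))
    den /= len(perms)
    return num / den, num, den
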