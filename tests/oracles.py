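"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the motif checker
slides a window and tests set membership directly; the alignment oracle is
a standalone affine-gap dynamic program; the greedy-clustering oracle
replays the clustering rule from a full pairwise identity matrix.
"""

from __future__ import annotations

import numpy as np

NEG = -1e9


def brute_force_scan(sequence: str, elements) -> list[int]:
    """1-based start positions of all windows satisfying every element set."""
    k = len(elements)
    out = []
    for start in range(len(sequence) - k + 1):
        if all(sequence[start + i] in el for i, el in enumerate(elements)):
            out.append(start + 1)
    return out


def gotoh_identity(a: str, b: str, open_: float = -10.0, ext: float = -0.5):
    """Global affine-gap DP: (optimal score, max identities among optima).

    Scoring: match +1, mismatch 0; a gap of length k costs open + (k-1)*ext.
    Ties in score are broken toward more identical pairs.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    Mi = np.zeros((n + 1, m + 1))
    Xi = np.zeros((n + 1, m + 1))
    Yi = np.zeros((n + 1, m + 1))
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext

    def best(cands):
        s = max(c[0] for c in cands)
        ident = max(c[1] for c in cands if c[0] >= s - 1e-9)
        return s, ident

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = 1.0 if a[i - 1] == b[j - 1] else 0.0
            s, ident = best(
                [(M[i - 1, j - 1], Mi[i - 1, j - 1]),
                 (X[i - 1, j - 1], Xi[i - 1, j - 1]),
                 (Y[i - 1, j - 1], Yi[i - 1, j - 1])]
            )
            M[i, j] = s + match
            Mi[i, j] = ident + (1 if match else 0)
            X[i, j], Xi[i, j] = best(
                [(M[i - 1, j] + open_, Mi[i - 1, j]),
                 (X[i - 1, j] + ext, Xi[i - 1, j]),
                 (Y[i - 1, j] + open_, Yi[i - 1, j])]
            )
            Y[i, j], Yi[i, j] = best(
                [(M[i, j - 1] + open_, Mi[i, j - 1]),
                 (Y[i, j - 1] + ext, Yi[i, j - 1]),
                 (X[i, j - 1] + open_, Xi[i, j - 1])]
            )
    return best([(M[n, m], Mi[n, m]), (X[n, m], Xi[n, m]), (Y[n, m], Yi[n, m])])


def greedy_cluster_oracle(records, threshold: float, identity_fn):
    """Replay the greedy rule from an exhaustive identity matrix.

    Returns a list of lists of member ids, in cluster-founding order.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    ident = {}
    for r1 in ordered:
        for r2 in ordered:
            if r1.id < r2.id:
                ident[(r1.id, r2.id)] = identity_fn(r1.sequence, r2.sequence)

    def lookup(x, y):
        if x == y:
            return 1.0
        key = (x, y) if x < y else (y, x)
        return ident[key]

    clusters: list[dict] = []
    for rec in ordered:
        for cluster in clusters:
            if lookup(rec.id, cluster["rep"]) >= threshold:
                cluster["members"].append(rec.id)
                break
        else:
            clusters.append({"rep": rec.id, "members": [rec.id]})
    return [c["members"] for c in clusters]
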