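"""Independent oracles shared across test modules."""

import numpy as np
from scipy.special import logsumexp

from parasdm.maxent import build_feature_space, compute_lambdas


def brute_force_beta(st, fc, rm, span=6.0, points=41, zooms=5):
    """Zooming grid-search oracle for the convex penalized objective.

    Independent of the fitting path: evaluates the objective directly on a
    shrinking lattice (keeping the |beta|-kink at zero in every candidate
    set) and returns the best lattice point, its value, and the objective.
    """
    space = build_feature_space(st, fc)
    lam = compute_lambdas(space, rm)
    Fp = space.matrix[space.presence_rows]
    Fb = space.matrix[~space.presence_rows]

    def obj(b):
        return float(-Fp.mean(axis=0) @ b + logsumexp(Fb @ b) + lam @ np.abs(b))

    J = space.matrix.shape[1]
    best = np.zeros(J)
    half = span
    for _ in range(zooms):
        axes = np.meshgrid(
            *[np.linspace(c - half, c + half, points) for c in best],
            indexing="ij",
        )
        flat = np.column_stack([a.ravel() for a in axes])
        flat = np.vstack([flat, np.zeros(J)])
        vals = np.array([obj(b) for b in flat])
        i = int(vals.argmin())
        best = flat[i]
        half = 2 * (2 * half / (points - 1))
    return best, obj(best), obj
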