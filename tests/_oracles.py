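"""Independent numerical oracles shared by the test modules."""

import numpy as np


def numeric_delta_se(stat_of_means, means, variances, ns, rel_h=1e-6):
    """Delta-method SE via central finite differences.

    ``stat_of_means`` maps a length-4 mean vector (C, A, B, AB order, or
    any fixed order matching ``means``) to the scalar statistic; the
    variance of the statistic is grad' diag(var_i/n_i) grad.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ns = np.asarray(ns, dtype=float)
    grad = np.zeros_like(means)
    for i in range(means.size):
        h = rel_h * means[i]
        up, dn = means.copy(), means.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (stat_of_means(up) - stat_of_means(dn)) / (2 * h)
    return float(np.sqrt(np.sum(grad ** 2 * variances / ns)))


def brute_force_t_percentile(zs, alpha):
    """Smallest order statistic t with #{z <= t}/B >= alpha, by scanning."""
    zs = sorted(zs)
    b = len(zs)
    for t in zs:
        if sum(z <= t for z in zs) / b >= alpha - 1e-12:
            return t
    return zs[-1]
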