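"""Independent oracles shared across tests: deliberately naive implementations
(quadrature, exhaustive search, pairwise counting) that the fast production
code is checked against."""

import numpy as np


def quadrature_posterior_1d(log_post, lo=-10.0, hi=10.0, n=20001):
    """Normalised 1-D posterior on a grid. Returns (grid, pdf, cdf, mean)."""
    grid = np.linspace(lo, hi, n)
    lp = np.array([log_post(b) for b in grid])
    lp -= lp.max()
    pdf = np.exp(lp)
    pdf /= np.trapezoid(pdf, grid)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    mean = float(np.trapezoid(grid * pdf, grid))
    return grid, pdf, cdf, mean


def hdi_exhaustive(samples, mass=0.95):
    """Exhaustive window search over the sorted samples: the HDI oracle."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + m - 1])
    return best[1], best[2]


def auc_pairwise(scores, labels):
    """Brute-force Mann-Whitney AUC: count all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ess_batch_means(chain, batch_size=None):
    """Batch-means ESS estimator for a single chain (oracle for the
    autocorrelation-based estimator)."""
    x = np.asarray(chain, dtype=float)
    n = x.size
    if batch_size is None:
        batch_size = int(np.floor(np.sqrt(n)))
    n_batches = n // batch_size
    trimmed = x[: n_batches * batch_size].reshape(n_batches, batch_size)
    batch_means = trimmed.mean(axis=1)
    var_bm = batch_size * batch_means.var(ddof=1)
    return n * x.var(ddof=1) / var_bm
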